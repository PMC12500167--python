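"""Class-balancing generation protocols.

Minority cell types are raised to the third quartile (Q3) of the class-size
distribution: a flow is fitted separately per cell type needing synthesis,
and exactly ``Q3 - observed`` synthetic cells are generated for each such
type, so the pooled real+synthetic count of every class is
``max(observed, Q3)``.  A label-free protocol generates as many unlabeled
cells as the test set from one flow fitted on the whole training matrix.
Proportional subsampling shrinks a dataset to ``n`` cells while preserving
the cell-type distribution by largest-remainder allocation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import CountMatrix, LabeledDataset
from .maf import Flow
from .moe import MoEConfig
from .train import TrainConfig, train_flow

logger = logging.getLogger(__name__)

__all__ = [
    "GenerationPlan", "q3_plan", "partition_by_type", "fit_per_type",
    "generate_balanced", "generate_matched", "proportional_subsample",
]


@dataclass
class GenerationPlan:
    """Per-cell-type synthetic sample targets derived from the Q3 rule."""

    targets: dict
    q3_value: int


def q3_plan(labels: np.ndarray) -> GenerationPlan:
    """Q3 balancing plan: Q3 is the linear-interpolation 0.75-quantile of
    the per-class counts, rounded half-up; each class's target is
    ``max(0, Q3 - observed)``."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    names, counts = np.unique(labels, return_counts=True)
    q3 = int(np.floor(np.quantile(counts, 0.75) + 0.5))
    targets = {name: max(0, q3 - int(c)) for name, c in zip(names.tolist(), counts)}
    return GenerationPlan(targets=targets, q3_value=q3)


def partition_by_type(data: LabeledDataset) -> dict:
    """Disjoint row-index sets per cell type, covering all rows."""
    return {label: np.flatnonzero(data.cell_types == label)
            for label in np.unique(data.cell_types)}


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31, reproducible from ``seed``."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def fit_per_type(data: LabeledDataset, config: TrainConfig,
                 plan: GenerationPlan | None = None, model_kind: str = "maf",
                 moe_config: MoEConfig | None = None,
                 audit: dict | None = None) -> dict:
    """Fit one flow per cell type that the plan asks synthesis for.

    Classes whose target is 0 are skipped; classes with fewer than 2 cells
    are skipped with a warning (upstream preprocessing removes classes under
    10 cells anyway).  If ``audit`` is given, the row indices each fit saw
    are recorded under the class label.
    """
    plan = plan or q3_plan(data.cell_types)
    partition = partition_by_type(data)
    needed = sorted(label for label, t in plan.targets.items() if t > 0)
    seeds = _spawn_seeds(config.seed, len(needed))
    models = {}
    for label, child_seed in zip(needed, seeds):
        rows = partition.get(label)
        if rows is None:
            raise ValueError(f"plan references unknown class {label!r}")
        if len(rows) < 2:
            warnings.warn(f"class {label!r} has {len(rows)} cell(s); skipping fit")
            continue
        if audit is not None:
            audit[label] = np.sort(rows)
        cfg = TrainConfig(**{**config.__dict__, "seed": child_seed})
        models[label] = train_flow(data.X[rows], cfg, model_kind=model_kind,
                                   moe_config=moe_config)
        logger.info("fitted %s flow for class %s on %d cells",
                    model_kind, label, len(rows))
    return models


def generate_balanced(models: dict, plan: GenerationPlan, seed: int,
                      gene_ids: list[str] | None = None) -> LabeledDataset:
    """Generate exactly ``plan.targets[label]`` synthetic cells per class
    from the per-class models; output rows carry the class label."""
    needed = sorted(label for label, t in plan.targets.items() if t > 0)
    missing = [label for label in needed if label not in models]
    if missing:
        raise ValueError(f"no model for class(es) {missing} with positive targets")
    blocks, labels = [], []
    seeds = _spawn_seeds(seed, len(needed))
    dim = None
    for label, child_seed in zip(needed, seeds):
        n = plan.targets[label]
        block = models[label].sample(n, seed=child_seed)
        dim = block.shape[1]
        blocks.append(block)
        labels.extend([label] * n)
    values = np.vstack(blocks) if blocks else np.zeros((0, dim or 0))
    genes = gene_ids or [f"gene{j}" for j in range(values.shape[1])]
    matrix = CountMatrix(values, genes,
                         [f"synth{i}" for i in range(values.shape[0])],
                         layer="lognorm")
    return LabeledDataset(matrix, np.array(labels, dtype=object).astype(str)
                          if labels else np.array([], dtype=str))


def generate_matched(model: Flow, n_test: int, seed: int) -> np.ndarray:
    """Label-free protocol: ``n_test`` synthetic rows from a single flow
    fitted on the full training matrix."""
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    return model.sample(n_test, seed=seed)


def proportional_subsample(data: LabeledDataset, n: int, seed: int) -> LabeledDataset:
    """Subsample ``n`` cells preserving the cell-type distribution.

    Per-type quotas are ``floor(n * p_type)``; the remaining cells go one
    each to the types with the largest fractional remainders (ties broken by
    larger class, then label order).  Rows are drawn uniformly without
    replacement within type, and no type is oversampled beyond its size.
    """
    if n > data.n_cells:
        raise ValueError(f"cannot subsample {n} of {data.n_cells} cells")
    partition = partition_by_type(data)
    labels = sorted(partition)
    sizes = np.array([len(partition[l]) for l in labels], dtype=float)
    exact = n * sizes / sizes.sum()
    quota = np.floor(exact).astype(int)
    remainder = exact - quota
    shortfall = n - quota.sum()
    order = sorted(range(len(labels)),
                   key=lambda i: (-remainder[i], -sizes[i], labels[i]))
    for i in order[:shortfall]:
        quota[i] += 1
    quota = np.minimum(quota, sizes.astype(int))
    # any capacity hit (cannot happen with exact proportions) is redistributed
    deficit = n - quota.sum()
    if deficit > 0:
        for i in order:
            room = int(sizes[i]) - quota[i]
            take = min(room, deficit)
            quota[i] += take
            deficit -= take
            if deficit == 0:
                break
    rng = np.random.default_rng(seed)
    chosen = [rng.choice(partition[label], size=q, replace=False)
              for label, q in zip(labels, quota)]
    idx = np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)
    return data.subset_cells(idx)
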