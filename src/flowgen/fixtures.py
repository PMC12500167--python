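"""Seeded negative-binomial simulator of imbalanced scRNA-seq datasets.

The simulator emulates the statistical structure the generative models and
the evaluation pipeline consume: overdispersed counts with high sparsity,
skewed cell-type sizes (geometric decay across types), per-type marker-gene
up-shifts, and an optional multiplicative batch effect.  Counts are drawn
gamma-Poisson (negative binomial with mean ``mu`` and variance
``mu + mu^2 / dispersion``), then thinned by Bernoulli dropout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CountMatrix, LabeledDataset

__all__ = ["FixtureConfig", "simulate_fixture"]


@dataclass
class FixtureConfig:
    """Parameters of the simulator.

    ``decay`` is the geometric ratio between consecutive class proportions;
    the default 0.368 gives a ~20:1 spread across four types.  ``marker_fold``
    multiplies the mean of a type's marker genes within that type.
    """

    n_cells: int = 2000
    n_genes: int = 200
    n_types: int = 4
    decay: float = 0.368
    markers_per_type: int = 10
    marker_fold: float = 4.0
    mean_scale: float = 0.5
    mean_sigma: float = 1.0
    dispersion: float = 2.0
    dropout: float = 0.3
    n_batches: int = 1
    batch_sigma: float = 0.0
    seed: int = 0

    def proportions(self) -> np.ndarray:
        p = self.decay ** np.arange(self.n_types)
        return p / p.sum()

    def validate(self) -> None:
        if min(self.n_cells, self.n_genes, self.n_types, self.n_batches) < 1:
            raise ValueError("counts must be positive")
        if not (0.0 < self.decay <= 1.0):
            raise ValueError("decay must be in (0, 1]")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.dispersion <= 0 or self.mean_scale <= 0:
            raise ValueError("dispersion and mean_scale must be positive")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError("more marker genes than genes")


def simulate_fixture(config: FixtureConfig) -> LabeledDataset:
    """Draw one dataset from the simulator; fully determined by the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    base_means = config.mean_scale * rng.lognormal(0.0, config.mean_sigma,
                                                   config.n_genes)
    sizes = rng.multinomial(config.n_cells, config.proportions())
    batch_factors = rng.lognormal(0.0, config.batch_sigma,
                                  (config.n_batches, config.n_genes)) \
        if config.batch_sigma > 0 else np.ones((config.n_batches, config.n_genes))

    counts = np.zeros((config.n_cells, config.n_genes))
    cell_types = np.empty(config.n_cells, dtype=object)
    batches = rng.integers(0, config.n_batches, config.n_cells)

    row = 0
    m = config.markers_per_type
    for k, size in enumerate(sizes):
        means = base_means.copy()
        means[k * m:(k + 1) * m] *= config.marker_fold
        mu = means[None, :] * batch_factors[batches[row:row + size]]
        lam = rng.gamma(config.dispersion, mu / config.dispersion)
        block = rng.poisson(lam).astype(np.float64)
        if config.dropout > 0:
            block *= rng.random(block.shape) >= config.dropout
        counts[row:row + size] = block
        cell_types[row:row + size] = f"type{k}"
        row += size

    matrix = CountMatrix(
        counts,
        gene_ids=[f"gene{j}" for j in range(config.n_genes)],
        cell_ids=[f"cell{i}" for i in range(config.n_cells)],
        layer="counts")
    batch_labels = np.array([f"batch{b}" for b in batches]) \
        if config.n_batches > 1 else None
    return LabeledDataset(matrix, cell_types.astype(str), batch_labels)
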