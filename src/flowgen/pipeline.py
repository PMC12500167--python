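"""Evaluation protocol: PC-50 representation, stratified cross-validation,
random-forest cell-type classification, benchmark orchestration, and the
top-N mutually-exclusive marker-gene filter.

The benchmark mirrors the protocol used to assess generative oversampling:
for each fold, flows are fitted per cell type on the training rows only, a
Q3-balanced synthetic pool is generated, discrepancy metrics are computed in
a 50-component PCA space fitted on the fold's real training matrix, and a
random forest is trained once on the original rows and once on the pooled
(real + synthetic) rows.  A structural audit asserts that no test row ever
reaches a generator or PCA fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .balance import fit_per_type, generate_balanced, q3_plan
from .io import LabeledDataset, select_hvg
from .metrics import (MetricReport, classification_scores, correlation_discrepancy,
                      mmd_rbf, per_class_recall, wasserstein_mean)
from .moe import MoEConfig
from .train import TrainConfig

logger = logging.getLogger(__name__)

__all__ = [
    "FoldSplit", "PCAProjection", "pc50_project", "stratified_kfold",
    "rf_classify", "BenchmarkConfig", "BenchmarkResult", "run_benchmark",
    "unique_top_degs", "LeakageError",
]


class LeakageError(RuntimeError):
    """A generator or representation fit saw rows outside the training set."""


@dataclass
class FoldSplit:
    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class PCAProjection:
    """A PCA basis fitted on one reference matrix."""

    components: np.ndarray        # (d, n_components)
    mean: np.ndarray
    explained_variance: np.ndarray
    fitted_on: str = "reference"

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.components.shape[0]:
            raise ValueError("feature mismatch with the fitted projection")
        return (X - self.mean) @ self.components


def pc50_project(reference: np.ndarray, queries=(), n_components: int = 50,
                 fitted_on: str = "reference"):
    """Fit PCA on the reference (real) matrix only and transform reference
    and queries with that single fit.

    The effective number of components is capped by the rank of the fitting
    data (components with numerically zero explained variance are dropped
    with a warning).
    """
    reference = np.atleast_2d(np.asarray(reference, dtype=np.float64))
    n, d = reference.shape
    k = min(n_components, n, d)
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(reference)
    ev = pca.explained_variance_
    keep = ev > max(ev.max(), 1e-300) * 1e-10
    if not keep.all():
        warnings.warn(f"reference rank limits projection to {int(keep.sum())} "
                      f"of {k} requested components")
    proj = PCAProjection(components=pca.components_[keep].T,
                         mean=pca.mean_,
                         explained_variance=ev[keep],
                         fitted_on=fitted_on)
    ref_p = proj.transform(reference)
    queries_p = [proj.transform(np.atleast_2d(q)) for q in queries]
    return proj, ref_p, queries_p


def stratified_kfold(labels: np.ndarray, k: int, seed: int,
                     stratify: bool = True) -> list[FoldSplit]:
    """Seeded k-fold split; stratified by label (default) so every cell type
    appears in every fold's training set.  Classes smaller than k are
    flagged by a warning."""
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if stratify:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < k:
            warnings.warn(f"smallest class has {counts.min()} < k={k} members")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    return [FoldSplit(i, np.sort(tr), np.sort(te))
            for i, (tr, te) in enumerate(splits)]


def rf_classify(train_X: np.ndarray, train_y: np.ndarray, test_X: np.ndarray,
                seed: int) -> np.ndarray:
    """100-tree random forest with the entropy split criterion and unlimited
    depth; returns one predicted label per test row."""
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training data covers a single class")
    clf = RandomForestClassifier(n_estimators=100, criterion="entropy",
                                 max_depth=None, random_state=seed)
    clf.fit(np.atleast_2d(train_X), train_y)
    return clf.predict(np.atleast_2d(test_X))


@dataclass
class BenchmarkConfig:
    """Knobs of :func:`run_benchmark`."""

    k: int = 5
    seed: int = 0
    n_hvg: int | None = None        # per-fold HVG selection on train rows
    n_pcs: int = 50
    train: TrainConfig = field(default_factory=TrainConfig)
    moe: MoEConfig = field(default_factory=MoEConfig)
    average: str = "macro"


@dataclass
class BenchmarkResult:
    per_fold: pd.DataFrame          # one row per (fold, arm)
    averages: pd.DataFrame          # mean over folds per arm
    recall_per_class: pd.DataFrame  # one row per (fold, arm, class)


def run_benchmark(data: LabeledDataset, model_kind: str = "maf",
                  config: BenchmarkConfig | None = None) -> BenchmarkResult:
    """Cross-validated evaluation of Q3-balanced flow oversampling.

    ``data`` must be a log-normalized labeled dataset.  Per fold the report
    carries two discrepancy arms — ``baseline`` (real train vs test) and
    ``balanced`` (real+synthetic pool vs test) — and two classification
    arms — ``original`` (RF on real train) and ``pooled`` (RF on
    real+synthetic), all in the fold's train-fitted PC space.
    """
    config = config or BenchmarkConfig()
    folds = stratified_kfold(data.cell_types, config.k, config.seed)
    rows, recall_rows = [], []
    for split in folds:
        train = data.subset_cells(split.train_idx)
        test = data.subset_cells(split.test_idx)

        if config.n_hvg is not None:
            hvg = select_hvg(train.matrix, config.n_hvg)
            train = train.subset_genes(hvg)
            test = test.subset_genes(hvg)

        audit: dict = {}
        plan = q3_plan(train.cell_types)
        models = fit_per_type(train, config.train, plan=plan,
                              model_kind=model_kind, moe_config=config.moe,
                              audit=audit)
        synth = generate_balanced(models, plan, seed=config.seed + split.fold,
                                  gene_ids=train.matrix.gene_ids)
        _audit_leakage(audit, split, n_train=train.n_cells)

        proj, train_p, (test_p, synth_p) = pc50_project(
            train.X, [test.X, synth.X if synth.n_cells else np.zeros((0, train.X.shape[1]))],
            n_components=config.n_pcs, fitted_on=f"fold{split.fold}-train")

        pooled_p = np.vstack([train_p, synth_p])
        pooled_y = np.concatenate([train.cell_types, synth.cell_types])

        for arm, ref in (("baseline", train_p), ("balanced", pooled_p)):
            report = MetricReport(
                wd=wasserstein_mean(ref, test_p),
                cd=correlation_discrepancy(ref, test_p),
                mmd=mmd_rbf(ref, test_p),
                metadata={"fold": split.fold, "arm": arm,
                          "representation": "pc50",
                          "n_real": len(train_p), "n_synth": len(synth_p),
                          "n_test": len(test_p)})
            rows.append(report.to_dict())

        for arm, (X, y) in (("original", (train_p, train.cell_types)),
                            ("pooled", (pooled_p, pooled_y))):
            pred = rf_classify(X, y, test_p, seed=config.seed)
            prec, rec, f1, acc = classification_scores(
                test.cell_types, pred, average=config.average)
            rows.append({"fold": split.fold, "arm": arm, "precision": prec,
                         "recall": rec, "f1": f1, "accuracy": acc,
                         "average": config.average, "representation": "pc50"})
            for label, value in per_class_recall(test.cell_types, pred).items():
                recall_rows.append({"fold": split.fold, "arm": arm,
                                    "cell_type": label, "recall": value})

    per_fold = pd.DataFrame(rows)
    numeric = per_fold.select_dtypes("number").columns.drop("fold")
    averages = per_fold.groupby("arm")[list(numeric)].mean().reset_index()
    recall_per_class = pd.DataFrame(recall_rows)
    return BenchmarkResult(per_fold, averages, recall_per_class)


def _audit_leakage(audit: dict, split: FoldSplit, n_train: int) -> None:
    """Generator fits index rows of the fold-local training matrix; assert
    every audited index is inside that matrix (hence inside the fold's
    training rows)."""
    for label, rows in audit.items():
        if len(rows) and (rows.min() < 0 or rows.max() >= n_train):
            raise LeakageError(
                f"generator for class {label!r} saw rows outside the training set")


def unique_top_degs(records, top_n: int = 20) -> dict:
    """Top differentially-expressed genes per cell type, made mutually
    exclusive across types.

    ``records`` is a DataFrame (columns gene, cell_type, p_adj, log2fc) or
    an iterable of mappings with those keys.  Records are filtered to
    adjusted p < 0.05 and log2FC > 1, ranked by descending log2FC (ties by
    smaller adjusted p, then gene id), cut to ``top_n`` per type, and any
    gene appearing in two or more types' top lists is dropped everywhere.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    if len(records) == 0:
        return {}
    required = {"gene", "cell_type", "p_adj", "log2fc"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"DEG table lacks column(s) {sorted(missing)}")
    kept = records[(records["p_adj"] < 0.05) & (records["log2fc"] > 1.0)]
    tops = {}
    for cell_type, group in kept.groupby("cell_type", sort=True):
        ranked = group.sort_values(["log2fc", "p_adj", "gene"],
                                   ascending=[False, True, True])
        tops[cell_type] = ranked["gene"].head(top_n).tolist()
    seen: dict = {}
    for genes in tops.values():
        for g in genes:
            seen[g] = seen.get(g, 0) + 1
    return {t: [g for g in genes if seen[g] == 1] for t, genes in tops.items()}
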