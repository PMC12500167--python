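"""Fidelity and performance metrics for real-vs-synthetic comparisons.

* **Correlation discrepancy (CD)** — mean absolute entrywise difference of
  the two datasets' Pearson gene-gene correlation matrices (diagonal
  included; zero-variance columns contribute correlation 0 by convention).
* **Wasserstein distance (WD)** — 1-D Wasserstein-1 per feature via the
  discrete empirical-CDF sum over pooled sorted unique values, averaged
  across features.
* **MMD** — biased V-statistic with an RBF kernel
  ``exp(-||x-y||^2 / (2 l^2))``, averaged over a list of length scales
  (default 0.005, 0.01, 0.1, 0.5, 1, 2); a linear kernel is selectable.
* **Classification scores** — precision/recall/F1 from per-class confusion
  counts (macro average by default), accuracy as the overall fraction
  correct.
* **Batch silhouette** — ``1 - |mean silhouette|`` computed with batch
  labels as clusters and Euclidean distances; near 1 means batches are well
  mixed.
* **RMSE** — root mean squared elementwise difference, with keyed-table
  alignment on the intersection of keys for interaction-mean comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "RBFConfig", "MetricReport", "correlation_discrepancy", "wasserstein_mean",
    "mmd_rbf", "classification_scores", "batch_silhouette", "rmse",
]

DEFAULT_SCALES = (0.005, 0.01, 0.1, 0.5, 1.0, 2.0)


@dataclass
class RBFConfig:
    """Kernel configuration for MMD; ``scales`` are the RBF length scales l
    in ``exp(-||x-y||^2 / (2 l^2))``."""

    scales: tuple = DEFAULT_SCALES
    kernel: str = "rbf"

    def __post_init__(self):
        if any(s <= 0 for s in self.scales):
            raise ValueError("length scales must be positive")


@dataclass
class MetricReport:
    """Metric values for one real-vs-synthetic comparison."""

    wd: float | None = None
    cd: float | None = None
    mmd: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    accuracy: float | None = None
    rmse: float | None = None
    batch_silhouette: float | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items()
               if k != "metadata" and v is not None}
        out.update(self.metadata)
        return out


def _check_columns(A: np.ndarray, B: np.ndarray):
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"column mismatch: {A.shape[1]} vs {B.shape[1]}")
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("empty input")
    return A, B


def _safe_corr(X: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of columns; zero-variance columns get
    correlation 0 everywhere (including their diagonal), with a warning."""
    std = X.std(axis=0)
    flat = std == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance column(s); "
                      "their correlations are defined as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    R[np.isnan(R)] = 0.0
    if flat.any():
        R[flat, :] = 0.0
        R[:, flat] = 0.0
    return R


def correlation_discrepancy(A: np.ndarray, B: np.ndarray) -> float:
    """Mean absolute difference of the Pearson correlation matrices of the
    two datasets' features (all d^2 entries, zero diagonal included)."""
    A, B = _check_columns(A, B)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("correlation needs at least 2 rows per dataset")
    return float(np.mean(np.abs(_safe_corr(A) - _safe_corr(B))))


def wasserstein_1d(a: np.ndarray, b: np.ndarray) -> float:
    """Discrete-CDF form of the 1-D Wasserstein-1 distance:
    ``sum_k |F(z_k) - G(z_k)| (z_{k+1} - z_k)`` over the pooled sorted
    unique values z."""
    a = np.sort(np.asarray(a, dtype=np.float64))
    b = np.sort(np.asarray(b, dtype=np.float64))
    z = np.unique(np.concatenate([a, b]))
    if len(z) < 2:
        return 0.0
    F = np.searchsorted(a, z[:-1], side="right") / len(a)
    G = np.searchsorted(b, z[:-1], side="right") / len(b)
    return float(np.sum(np.abs(F - G) * np.diff(z)))


def wasserstein_mean(A: np.ndarray, B: np.ndarray) -> float:
    """Per-feature 1-D Wasserstein-1 distance, averaged across features."""
    A, B = _check_columns(A, B)
    return float(np.mean([wasserstein_1d(A[:, j], B[:, j])
                          for j in range(A.shape[1])]))


def mmd_rbf(A: np.ndarray, B: np.ndarray,
            config: RBFConfig | None = None) -> float:
    """Biased V-statistic MMD^2 ``mean(K_AA) + mean(K_BB) - 2 mean(K_AB)``
    (diagonal terms included, so identical multisets give exactly 0),
    averaged over the configured kernel length scales."""
    config = config or RBFConfig()
    A, B = _check_columns(A, B)
    d2_aa = _sq_dists(A, A)
    d2_bb = _sq_dists(B, B)
    d2_ab = _sq_dists(A, B)
    if config.kernel == "linear":
        return float((A @ A.T).mean() + (B @ B.T).mean() - 2 * (A @ B.T).mean())
    if config.kernel != "rbf":
        raise ValueError(f"unknown kernel {config.kernel!r}")
    vals = []
    for scale in config.scales:
        gamma = 1.0 / (2.0 * scale ** 2)
        vals.append(np.exp(-gamma * d2_aa).mean()
                    + np.exp(-gamma * d2_bb).mean()
                    - 2.0 * np.exp(-gamma * d2_ab).mean())
    return float(np.mean(vals))


def _sq_dists(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    nx = (X ** 2).sum(axis=1)
    ny = (Y ** 2).sum(axis=1)
    d2 = nx[:, None] + ny[None, :] - 2.0 * (X @ Y.T)
    return np.maximum(d2, 0.0)


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray, label) -> dict:
    """One-vs-rest TP/FP/FN/TN counts for ``label``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == label) & (y_pred == label)))
    fp = int(np.sum((y_true != label) & (y_pred == label)))
    fn = int(np.sum((y_true == label) & (y_pred != label)))
    tn = int(np.sum((y_true != label) & (y_pred != label)))
    return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


def classification_scores(y_true: np.ndarray, y_pred: np.ndarray,
                          average: str = "macro") -> tuple:
    """(precision, recall, F1, accuracy) from per-class confusion counts.

    Precision of a class absent from the predictions is defined as 0 (and
    logged).  ``average`` is macro (default), micro, or weighted; accuracy
    is always the overall fraction correct.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    per_class = []
    weights = []
    tp_sum = fp_sum = fn_sum = 0
    for label in labels:
        c = confusion_counts(y_true, y_pred, label)
        tp_sum, fp_sum, fn_sum = tp_sum + c["TP"], fp_sum + c["FP"], fn_sum + c["FN"]
        if c["TP"] + c["FP"] == 0:
            logger.info("class %s never predicted; precision defined as 0", label)
        prec = c["TP"] / (c["TP"] + c["FP"]) if c["TP"] + c["FP"] else 0.0
        rec = c["TP"] / (c["TP"] + c["FN"]) if c["TP"] + c["FN"] else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class.append((prec, rec, f1))
        weights.append(c["TP"] + c["FN"])
    accuracy = float(np.mean(y_true == y_pred))
    if average == "macro":
        prec, rec, f1 = np.mean(per_class, axis=0)
    elif average == "weighted":
        w = np.asarray(weights, dtype=float)
        prec, rec, f1 = (np.asarray(per_class) * w[:, None]).sum(axis=0) / w.sum()
    elif average == "micro":
        prec = tp_sum / (tp_sum + fp_sum) if tp_sum + fp_sum else 0.0
        rec = tp_sum / (tp_sum + fn_sum) if tp_sum + fn_sum else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    else:
        raise ValueError(f"unknown average {average!r}")
    return float(prec), float(rec), float(f1), accuracy


def per_class_recall(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Recall per true class; convenience for minority-class analyses."""
    out = {}
    for label in np.unique(np.asarray(y_true)):
        c = confusion_counts(y_true, y_pred, label)
        out[label] = c["TP"] / (c["TP"] + c["FN"]) if c["TP"] + c["FN"] else 0.0
    return out


def batch_silhouette(X: np.ndarray, batches: np.ndarray) -> float:
    """``1 - |S|`` where S is the mean silhouette of the samples with batch
    labels as clusters (Euclidean distances).  Values near 1 indicate well
    mixed batches."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    batches = np.asarray(batches)
    names, counts = np.unique(batches, return_counts=True)
    if len(names) < 2:
        raise ValueError("batch_silhouette needs at least 2 batches")
    if counts.min() < 2:
        raise ValueError("every batch needs at least 2 members")
    S = silhouette_score(X, batches, metric="euclidean")
    return float(1.0 - abs(S))


def rmse(A, B) -> float:
    """Root mean squared difference.

    Plain arrays must share a shape.  ``pandas`` Series/DataFrames are
    treated as keyed tables: they are aligned on the intersection of their
    keys (logged), and an empty overlap is an error.
    """
    if isinstance(A, (pd.Series, pd.DataFrame)) or isinstance(B, (pd.Series, pd.DataFrame)):
        A = pd.Series(A) if not isinstance(A, (pd.Series, pd.DataFrame)) else A
        B = pd.Series(B) if not isinstance(B, (pd.Series, pd.DataFrame)) else B
        if isinstance(A, pd.DataFrame):
            A = A.stack()
        if isinstance(B, pd.DataFrame):
            B = B.stack()
        shared = A.index.intersection(B.index)
        if len(shared) == 0:
            raise ValueError("keyed RMSE: no overlapping keys")
        logger.info("keyed RMSE over %d shared key(s)", len(shared))
        a = A.loc[shared].to_numpy(dtype=np.float64)
        b = B.loc[shared].to_numpy(dtype=np.float64)
    else:
        a = np.asarray(A, dtype=np.float64)
        b = np.asarray(B, dtype=np.float64)
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
        if a.size == 0:
            raise ValueError("empty input")
    return float(np.sqrt(np.mean((a - b) ** 2)))
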