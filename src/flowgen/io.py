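"""Expression-matrix containers, file formats and preprocessing.

Cells are rows and genes are columns everywhere in memory.  On disk the
Matrix Market convention is the 10x one — genes x cells — with ``genes.tsv``
/ ``barcodes.tsv`` / optional ``labels.tsv`` sidecars; dense CSV is
cells x genes with a gene-id header and a leading cell-id column.

Preprocessing follows the usual single-cell recipe: drop rare cell-type
classes, filter genes expressed in too few cells then cells expressing too
few genes, library-size normalize with a log1p transform, and keep the most
variable genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix", "LabeledDataset", "ParseError",
    "read_matrix", "write_matrix", "read_dataset", "write_dataset",
    "qc_filter", "drop_rare_classes", "normalize_log", "select_hvg",
    "PreprocessParams", "preprocess_pipeline",
]


class ParseError(ValueError):
    """A file could not be parsed or its sidecars disagree in shape."""


def _infer_layer(values: np.ndarray) -> str:
    """Non-negative integer-valued matrices are counts; anything else is
    taken to be log-normalized."""
    if values.size and values.min() >= 0 and np.all(values == np.round(values)):
        return "counts"
    return "lognorm"


@dataclass
class CountMatrix:
    """A cells x genes expression matrix with identifier sidecars.

    ``layer`` records whether values are raw counts or log-normalized.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str = "counts"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        n_cells, n_genes = self.values.shape
        if n_genes != len(self.gene_ids):
            raise ParseError(
                f"matrix has {n_genes} genes but {len(self.gene_ids)} gene ids")
        if n_cells != len(self.cell_ids):
            raise ParseError(
                f"matrix has {n_cells} cells but {len(self.cell_ids)} cell ids")
        if self.layer == "counts" and self.values.size and self.values.min() < 0:
            raise ParseError("counts layer contains negative values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(self, cell_idx=None, gene_idx=None) -> "CountMatrix":
        cell_idx = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        gene_idx = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        return CountMatrix(
            self.values[np.ix_(cell_idx, gene_idx)],
            [self.gene_ids[i] for i in gene_idx],
            [self.cell_ids[i] for i in cell_idx],
            layer=self.layer)


@dataclass
class LabeledDataset:
    """A :class:`CountMatrix` plus per-cell type labels and optional batch
    labels — the currency every stage of the package trades in."""

    matrix: CountMatrix
    cell_types: np.ndarray
    batches: np.ndarray | None = None

    def __post_init__(self):
        self.cell_types = np.asarray(self.cell_types)
        if len(self.cell_types) != self.matrix.n_cells:
            raise ParseError(
                f"{len(self.cell_types)} labels for {self.matrix.n_cells} cells")
        if self.batches is not None:
            self.batches = np.asarray(self.batches)
            if len(self.batches) != self.matrix.n_cells:
                raise ParseError(
                    f"{len(self.batches)} batch labels for {self.matrix.n_cells} cells")

    @property
    def X(self) -> np.ndarray:
        return self.matrix.values

    @property
    def n_cells(self) -> int:
        return self.matrix.n_cells

    def class_counts(self) -> dict:
        labels, counts = np.unique(self.cell_types, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset_cells(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            self.matrix.subset(cell_idx=idx),
            self.cell_types[idx],
            None if self.batches is None else self.batches[idx])

    def subset_genes(self, idx) -> "LabeledDataset":
        return LabeledDataset(self.matrix.subset(gene_idx=np.asarray(idx)),
                              self.cell_types, self.batches)


# --------------------------------------------------------------------- io
def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        raise ParseError(f"missing sidecar file: {path}")
    return [line.split("\t")[0].strip() for line in
            path.read_text().splitlines() if line.strip()]


def read_matrix(path, format: str = "mtx") -> CountMatrix:
    """Read an expression matrix.

    ``mtx``: Matrix Market file stored genes x cells, transposed to
    cells x genes on load, with ``genes.tsv`` and ``barcodes.tsv`` sidecars
    next to it.  ``csv``: dense cells x genes table with a gene-id header
    row and a cell-id first column.
    """
    path = Path(path)
    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ParseError(f"cannot parse Matrix Market file {path}: {exc}") from exc
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=np.float64).T  # genes x cells on disk
        genes = _read_lines(path.parent / "genes.tsv")
        cells = _read_lines(path.parent / "barcodes.tsv")
        return CountMatrix(values, genes, cells, layer=_infer_layer(values))
    if format == "csv":
        try:
            frame = pd.read_csv(path, index_col=0)
        except Exception as exc:
            raise ParseError(f"cannot parse CSV file {path}: {exc}") from exc
        values = frame.to_numpy(dtype=np.float64)
        return CountMatrix(values,
                           [str(g) for g in frame.columns],
                           [str(c) for c in frame.index],
                           layer=_infer_layer(values))
    raise ValueError(f"unknown format {format!r}")


def write_matrix(data: CountMatrix, path, format: str = "mtx") -> None:
    """Write a matrix in the conventions of :func:`read_matrix` (lossless
    round-trip of values and ids)."""
    path = Path(path)
    if format == "mtx":
        path.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(data.values.T))
        (path.parent / "genes.tsv").write_text("\n".join(data.gene_ids) + "\n")
        (path.parent / "barcodes.tsv").write_text("\n".join(data.cell_ids) + "\n")
    elif format == "csv":
        frame = pd.DataFrame(data.values, index=data.cell_ids, columns=data.gene_ids)
        frame.to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_dataset(directory, format: str = "mtx") -> LabeledDataset:
    """Read matrix + ``labels.tsv`` (cell type, optional batch column)."""
    directory = Path(directory)
    matrix = read_matrix(directory / ("matrix.mtx" if format == "mtx" else "matrix.csv"),
                         format=format)
    labels_path = directory / "labels.tsv"
    if not labels_path.exists():
        raise ParseError(f"missing sidecar file: {labels_path}")
    table = pd.read_csv(labels_path, sep="\t", header=None)
    if len(table) != matrix.n_cells:
        raise ParseError(
            f"{labels_path} has {len(table)} rows for {matrix.n_cells} cells")
    batches = table.iloc[:, 1].to_numpy() if table.shape[1] > 1 else None
    return LabeledDataset(matrix, table.iloc[:, 0].to_numpy(), batches)


def write_dataset(data: LabeledDataset, directory, format: str = "mtx") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_matrix(data.matrix,
                 directory / ("matrix.mtx" if format == "mtx" else "matrix.csv"),
                 format=format)
    cols = {"cell_type": data.cell_types}
    if data.batches is not None:
        cols["batch"] = data.batches
    pd.DataFrame(cols).to_csv(directory / "labels.tsv", sep="\t",
                              header=False, index=False)


# ------------------------------------------------------------ preprocessing
def qc_filter(data: CountMatrix, min_cells: int = 100,
              min_genes: int = 100) -> CountMatrix:
    """Quality-control filter: first drop genes detected in fewer than
    ``min_cells`` cells, then drop cells expressing fewer than ``min_genes``
    of the remaining genes (single pass, in that order)."""
    if data.layer != "counts":
        raise ValueError("qc_filter expects a counts layer")
    detected = (data.values > 0).sum(axis=0)
    gene_keep = np.flatnonzero(detected >= min_cells)
    trimmed = data.subset(gene_idx=gene_keep)
    expressed = (trimmed.values > 0).sum(axis=1)
    cell_keep = np.flatnonzero(expressed >= min_genes)
    out = trimmed.subset(cell_idx=cell_keep)
    logger.info("qc_filter removed %d genes and %d cells",
                data.n_genes - out.n_genes, data.n_cells - out.n_cells)
    if out.n_genes == 0 or out.n_cells == 0:
        raise ValueError("qc_filter removed everything; thresholds too strict")
    return out


def qc_filter_labeled(data: LabeledDataset, min_cells: int = 100,
                      min_genes: int = 100) -> LabeledDataset:
    """Label-preserving wrapper around :func:`qc_filter`."""
    detected = (data.X > 0).sum(axis=0)
    gene_keep = np.flatnonzero(detected >= min_cells)
    trimmed = data.subset_genes(gene_keep)
    expressed = (trimmed.X > 0).sum(axis=1)
    cell_keep = np.flatnonzero(expressed >= min_genes)
    out = trimmed.subset_cells(cell_keep)
    if out.matrix.n_genes == 0 or out.n_cells == 0:
        raise ValueError("qc_filter removed everything; thresholds too strict")
    return out


def drop_rare_classes(data: LabeledDataset, min_count: int = 10) -> LabeledDataset:
    """Remove cell-type classes represented by fewer than ``min_count``
    cells, with their cells."""
    counts = data.class_counts()
    removed = {k: v for k, v in counts.items() if v < min_count}
    for label, count in removed.items():
        logger.info("dropping class %s with %d cells", label, count)
    keep = np.flatnonzero(~np.isin(data.cell_types, list(removed)))
    if len(keep) == 0:
        raise ValueError("drop_rare_classes removed every cell")
    return data.subset_cells(keep)


def normalize_log(data: CountMatrix) -> CountMatrix:
    """Library-size normalization followed by log1p.

    The size factor of a cell is its library size divided by the median
    library size; values become ``log1p(count / factor)``.  Cells with an
    empty library are removed with a warning.  Externally computed factors
    (e.g. pooled deconvolution factors) may be passed to
    :func:`normalize_log_with_factors` instead.
    """
    if data.layer != "counts":
        raise ValueError("normalize_log expects a counts layer")
    lib = data.values.sum(axis=1)
    keep = np.flatnonzero(lib > 0)
    if len(keep) < data.n_cells:
        warnings.warn(f"removing {data.n_cells - len(keep)} zero-library cell(s)")
        data = data.subset(cell_idx=keep)
        lib = lib[keep]
    factors = lib / np.median(lib)
    return normalize_log_with_factors(data, factors)


def normalize_log_with_factors(data: CountMatrix, factors: np.ndarray) -> CountMatrix:
    factors = np.asarray(factors, dtype=np.float64)
    if factors.shape != (data.n_cells,) or np.any(factors <= 0):
        raise ValueError("need one positive size factor per cell")
    values = np.log1p(data.values / factors[:, None])
    return CountMatrix(values, data.gene_ids, data.cell_ids, layer="lognorm")


def select_hvg(train: CountMatrix, n: int = 3000) -> np.ndarray:
    """Indices of the ``n`` most variable genes of a log-normalized training
    matrix (per-gene variance ranking, ties broken by gene id).  The same
    index set is then applied to test/synthetic matrices."""
    if train.layer != "lognorm":
        raise ValueError("select_hvg expects a lognorm layer")
    if n > train.n_genes:
        warnings.warn(f"requested {n} HVGs but only {train.n_genes} genes; keeping all")
        n = train.n_genes
    var = train.values.var(axis=0)
    order = sorted(range(train.n_genes), key=lambda i: (-var[i], train.gene_ids[i]))
    return np.array(sorted(order[:n]), dtype=np.intp)


@dataclass
class PreprocessParams:
    min_class: int = 10
    min_cells: int = 100
    min_genes: int = 100
    n_hvg: int = 3000


def preprocess_pipeline(data: LabeledDataset,
                        params: PreprocessParams | None = None) -> LabeledDataset:
    """Standard ordering: drop rare classes -> QC filter -> normalize/log ->
    HVG selection.  Each step logs the shapes before and after."""
    params = params or PreprocessParams()

    def log_step(name, ds):
        logger.info("%s -> %d cells x %d genes", name, ds.n_cells, ds.matrix.n_genes)

    data = drop_rare_classes(data, params.min_class)
    log_step("drop_rare_classes", data)
    data = qc_filter_labeled(data, params.min_cells, params.min_genes)
    log_step("qc_filter", data)
    normed = normalize_log(data.matrix)
    kept = [data.matrix.cell_ids.index(c) for c in normed.cell_ids] \
        if normed.n_cells != data.n_cells else np.arange(data.n_cells)
    data = LabeledDataset(normed, data.cell_types[kept],
                          None if data.batches is None else data.batches[kept])
    log_step("normalize_log", data)
    hvg = select_hvg(data.matrix, params.n_hvg)
    data = data.subset_genes(hvg)
    log_step("select_hvg", data)
    return data
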