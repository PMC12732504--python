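"""Count-matrix I/O, filtering, normalization, HVG selection and data splits.

Implements the uniform preprocessing applied before training the
negative-binomial VAE: cells are retained if they have at least
``min_nonzero_genes`` non-zero genes, at least ``min_total_counts`` total
counts and fewer than ``max_nonzero_genes`` non-zero genes; genes with
non-zero counts in fewer than ``min_cells`` cells are dropped.  Raw counts
are scaled by the mean count per cell and log1p-transformed for highly
variable gene (HVG) selection; the inverse transform recovers the raw counts
exactly, which remain the reconstruction targets for the count likelihood.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class DataError(ValueError):
    """Raised for malformed inputs or empty filtering results."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Cells × genes matrix of non-negative integer UMI counts.

    Attributes
    ----------
    counts
        Dense ``(n_cells, n_genes)`` integer array.
    gene_ids, cell_ids
        Ordered, duplicate-free identifier lists matching the axes.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if sp.issparse(self.counts):  # pragma: no cover - defensive
            self.counts = self.counts.toarray()
        if self.counts.ndim != 2:
            raise DataError("counts must be a 2-D cells × genes matrix")
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise DataError(
                f"shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cell ids × {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise DataError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise DataError("duplicate gene ids")
        if np.any(self.counts < 0):
            raise DataError("negative count entries")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded, atol=1e-8):
                raise DataError("non-integer count entries")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, idx: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.counts[idx],
            self.gene_ids,
            [self.cell_ids[i] for i in np.atleast_1d(idx)],
        )

    def subset_genes(self, idx: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.counts[:, idx],
            [self.gene_ids[i] for i in np.atleast_1d(idx)],
            self.cell_ids,
        )


@dataclass
class NormalizedMatrix:
    """Mean-scaled, log1p-transformed expression with exact inverse.

    ``values[c, g] = log1p(counts[c, g] / scale_factors[c])`` where the scale
    factor is the cell's mean count across genes.  ``inverse_transform``
    recovers the source counts exactly (integer equality after rounding).
    """

    values: np.ndarray
    scale_factors: np.ndarray
    source: CountMatrix

    @property
    def gene_ids(self) -> list[str]:
        return self.source.gene_ids

    @property
    def cell_ids(self) -> list[str]:
        return self.source.cell_ids

    def inverse_transform(self) -> np.ndarray:
        raw = np.expm1(self.values) * self.scale_factors[:, None]
        return np.rint(raw).astype(np.int64)


@dataclass
class LabelTable:
    """Per-cell labels: binary condition or continuous covariate.

    Missing labels are ``NaN``; ``kind`` is ``"binary"`` or ``"continuous"``.
    """

    cell_ids: list[str]
    labels: np.ndarray
    kind: Literal["binary", "continuous"]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if len(self.cell_ids) != len(self.labels):
            raise DataError("cell_ids and labels length mismatch")
        if self.kind == "binary":
            observed = self.labels[~np.isnan(self.labels)]
            if not np.all(np.isin(observed, (0.0, 1.0))):
                raise DataError("binary labels must be 0/1 or missing")

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.labels)

    def align_to(self, cell_ids: Sequence[str]) -> "LabelTable":
        """Reorder/subset to the given cell ids; absent cells become missing."""
        lookup = dict(zip(self.cell_ids, self.labels))
        vals = np.array([lookup.get(c, np.nan) for c in cell_ids], dtype=float)
        return LabelTable(list(cell_ids), vals, self.kind)


@dataclass
class SplitAssignment:
    """Train/val/test partition of cells, seed-deterministic."""

    partition: np.ndarray  # array of {"train","val","test"} per cell
    seed: int
    fractions: tuple[float, float, float] = (0.82, 0.09, 0.09)

    def indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.partition == name)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def read_counts(path: str, format: Literal["mtx_dir", "h5ad", "dense_tsv"]) -> CountMatrix:
    """Read a count matrix from disk.

    ``mtx_dir`` expects ``matrix.mtx`` (genes × cells, CellRanger layout),
    ``genes.tsv`` and ``barcodes.tsv`` inside a directory.  ``h5ad`` reads
    ``adata.X`` (or the ``"counts"`` layer when present).  ``dense_tsv`` is a
    cells × genes table with gene columns and cell-id index.
    """
    if not os.path.exists(path):
        raise DataError(f"path does not exist: {path}")
    if format == "mtx_dir":
        mtx = os.path.join(path, "matrix.mtx")
        try:
            mat = scipy.io.mmread(mtx)
        except Exception as exc:
            raise DataError(f"malformed Matrix Market file {mtx}: {exc}") from exc
        genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t", header=None)
        barcodes = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t", header=None)
        gene_ids = genes.iloc[:, 0].astype(str).tolist()
        cell_ids = barcodes.iloc[:, 0].astype(str).tolist()
        counts = np.asarray(sp.coo_matrix(mat).todense()).T  # genes × cells on disk
    elif format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.layers["counts"] if "counts" in adata.layers else adata.X
        counts = X.toarray() if sp.issparse(X) else np.asarray(X)
        gene_ids = adata.var_names.astype(str).tolist()
        cell_ids = adata.obs_names.astype(str).tolist()
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = df.to_numpy()
        gene_ids = df.columns.astype(str).tolist()
        cell_ids = df.index.astype(str).tolist()
    else:
        raise DataError(f"unknown format: {format}")
    if counts.size == 0 or counts.shape[0] == 0:
        raise DataError("no cells in input")
    return CountMatrix(counts, gene_ids, cell_ids)


def read_labels(path: str, kind: Literal["binary", "continuous"]) -> LabelTable:
    """Read a two-column TSV (cell_id, label); empty fields mark missing."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"], dtype={0: str})
    labels = pd.to_numeric(df["label"], errors="coerce").to_numpy(dtype=float)
    return LabelTable(df["cell_id"].tolist(), labels, kind)


def write_counts_mtx(cm: CountMatrix, out_dir: str) -> None:
    """Write a CountMatrix as a genes × cells Matrix Market directory."""
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(os.path.join(out_dir, "matrix.mtx"), sp.coo_matrix(cm.counts.T))
    pd.Series(cm.gene_ids).to_csv(
        os.path.join(out_dir, "genes.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(cm.cell_ids).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", header=False, index=False
    )


def write_labels(lt: LabelTable, path: str) -> None:
    vals = ["" if np.isnan(v) else (repr(float(v)) if lt.kind == "continuous" else str(int(v))) for v in lt.labels]
    pd.DataFrame({"cell_id": lt.cell_ids, "label": vals}).to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_cells(
    cm: CountMatrix,
    min_nonzero_genes: int = 200,
    min_total_counts: int = 500,
    max_nonzero_genes: int = 5000,
) -> CountMatrix:
    """Keep cells with ≥ min_nonzero_genes non-zero genes, ≥ min_total_counts
    total counts, and strictly fewer than max_nonzero_genes non-zero genes."""
    if min_nonzero_genes > max_nonzero_genes:
        raise DataError("min_nonzero_genes exceeds max_nonzero_genes")
    nonzero = (cm.counts > 0).sum(axis=1)
    totals = cm.counts.sum(axis=1)
    keep = (nonzero >= min_nonzero_genes) & (totals >= min_total_counts) & (nonzero < max_nonzero_genes)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise DataError("empty result: no cells survive filtering")
    return cm.subset_cells(idx)


def filter_genes(cm: CountMatrix, min_cells: int = 5) -> CountMatrix:
    """Drop genes with non-zero counts in fewer than ``min_cells`` cells."""
    if min_cells < 1:
        raise DataError("min_cells must be ≥ 1")
    n_expressing = (cm.counts > 0).sum(axis=0)
    idx = np.flatnonzero(n_expressing >= min_cells)
    if idx.size == 0:
        raise DataError("empty result: no genes survive filtering")
    return cm.subset_genes(idx)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def cell_scale_factors(counts: np.ndarray) -> np.ndarray:
    """Per-cell scale factor: the cell's mean count across genes."""
    return counts.sum(axis=1) / counts.shape[1]


def normalize_log1p(cm: CountMatrix) -> NormalizedMatrix:
    """Scale each cell by its mean count across genes, then log1p."""
    scale = cell_scale_factors(cm.counts)
    if np.any(scale <= 0):
        raise DataError("all-zero cell encountered; run filter_cells first")
    values = np.log1p(cm.counts / scale[:, None])
    return NormalizedMatrix(values, scale, cm)


# ---------------------------------------------------------------------------
# HVG selection
# ---------------------------------------------------------------------------


def dispersion_statistic(values: np.ndarray, n_bins: int = 20):
    """Binned normalized dispersion (Seurat flavor) of log-normalized data.

    Dispersion is var/mean of the de-logged values; genes are binned by mean
    expression and the dispersion z-scored within each bin.  Bins with a
    single gene or zero spread get normalized dispersion 0 (no evidence of
    excess variability); zero-variance genes always rank last.

    Returns ``(normalized_dispersion, raw_dispersion)``.
    """
    X = np.expm1(values)
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
    edges = np.quantile(mean, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, mean, side="right") - 1, 0, n_bins - 1)
    norm = np.zeros_like(disp)
    for b in np.unique(bins):
        in_bin = bins == b
        if in_bin.sum() < 2:
            continue
        sd = disp[in_bin].std(ddof=1)
        if sd > 0:
            norm[in_bin] = (disp[in_bin] - disp[in_bin].mean()) / sd
    norm = np.where(var > 0, norm, -np.inf)
    return norm, disp


def select_hvgs(
    nm: NormalizedMatrix,
    n_top: int,
    force_include: Sequence[str] = (),
    n_bins: int = 20,
) -> np.ndarray:
    """Select the ``n_top`` most variable genes by the binned normalized
    dispersion; forced genes always enter the selection, displacing the
    lowest-ranked picks.  Returns gene indices in the original gene order.
    """
    if n_top > len(nm.gene_ids):
        raise DataError("n_top exceeds the number of genes")
    unknown = [g for g in force_include if g not in nm.gene_ids]
    if unknown:
        raise DataError(f"forced genes not present: {unknown}")
    if n_top == len(nm.gene_ids):
        return np.arange(len(nm.gene_ids))
    norm, raw = dispersion_statistic(nm.values.astype(np.float64), n_bins)
    # rank by normalized then raw dispersion, deterministic index tie-break
    ranked = np.lexsort((np.arange(len(norm)), -raw, -norm))
    selected = list(ranked[:n_top])
    gene_pos = {g: i for i, g in enumerate(nm.gene_ids)}
    forced_idx = [gene_pos[g] for g in force_include]
    for fi in forced_idx:
        if fi not in selected:
            # displace the lowest-ranked non-forced selection
            for j in range(len(selected) - 1, -1, -1):
                if selected[j] not in forced_idx:
                    selected[j] = fi
                    break
    return np.sort(np.array(selected))


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_data(
    cm: CountMatrix,
    fractions: tuple[float, float, float] = (0.82, 0.09, 0.09),
    seed: int = 0,
) -> SplitAssignment:
    """Random 82/9/9 train/val/test split: floor sizes for val and test, the
    remainder to train; contiguous assignment over a seeded permutation."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise DataError("fractions must sum to 1")
    n = cm.n_cells
    if n < 3:
        raise DataError("need at least 3 cells to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    partition = np.empty(n, dtype=object)
    partition[perm[:n_train]] = "train"
    partition[perm[n_train : n_train + n_val]] = "val"
    partition[perm[n_train + n_val :]] = "test"
    return SplitAssignment(partition, seed, fractions)
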