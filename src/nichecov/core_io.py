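"""Data containers and text I/O for count matrices, coordinates and labels.

Count matrices are stored cells-by-genes. Sparse inputs (MatrixMarket) are
kept sparse internally; dense delimited files are read with pandas. All
result tables are plain :class:`pandas.DataFrame` objects and are exported as
delimited text with full floating-point precision so that a write/read round
trip is lossless to 1e-12.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

NOT_MAPPED = "NM"

__all__ = [
    "CountMatrix",
    "SpatialDataset",
    "ReferenceDataset",
    "load_counts",
    "load_coords",
    "load_labels",
    "align_shared_genes",
    "export_table",
    "read_table",
    "NOT_MAPPED",
]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        dup = pd.Series(ids).value_counts()
        dup = dup[dup > 1].index.tolist()[:5]
        raise ValueError(f"duplicate {what} ids: {dup}")


@dataclass
class CountMatrix:
    """Cells-by-genes non-negative count matrix with row/column identifiers.

    ``values`` may be a dense ndarray or any scipy sparse matrix; sparsity is
    preserved. Invariants (non-negativity, id uniqueness, shape agreement)
    are checked on construction.
    """

    values: "np.ndarray | sp.spmatrix"
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n, g = self.values.shape
        if n != len(self.cell_ids):
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if g != len(self.gene_ids):
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} columns")
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if self.min() < 0:
            raise ValueError("count matrix contains negative entries")

    # -- basic accessors -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def min(self) -> float:
        if sp.issparse(self.values):
            return self.values.min() if self.values.nnz else 0.0
        return float(self.values.min()) if self.values.size else 0.0

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def cell_totals(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.sum(axis=1)).ravel()
        return self.values.sum(axis=1)

    def gene_totals(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.sum(axis=0)).ravel()
        return self.values.sum(axis=0)

    # -- subsetting ------------------------------------------------------
    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        """Restrict to ``genes`` in the given order (exact string match)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        idx = np.array([index[g] for g in genes], dtype=int)
        vals = self.values.tocsc()[:, idx].tocsr() if sp.issparse(self.values) else self.values[:, idx]
        return CountMatrix(vals, self.cell_ids.copy(), np.asarray(genes, dtype=object))

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        vals = self.values.tocsr()[idx] if sp.issparse(self.values) else self.values[idx]
        return CountMatrix(vals, self.cell_ids[idx], self.gene_ids.copy())


@dataclass
class SpatialDataset:
    """Segmented spatial counts with 2D cell-centroid coordinates.

    ``coords`` is cells-by-2 in the length units of the input file; all
    distance thresholds downstream are expressed in those units. ``labels``
    is filled by the annotation module (sentinel ``'NM'`` marks unmapped
    cells).
    """

    counts: CountMatrix
    coords: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n_cells, 2) array")
        if self.coords.shape[0] != self.counts.n_cells:
            raise ValueError("coords row count does not match cell count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != self.counts.n_cells:
                raise ValueError("labels length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.counts.n_cells


@dataclass
class ReferenceDataset:
    """scRNA-seq reference counts with per-cell cluster (cell-type) labels."""

    counts: CountMatrix
    cluster_labels: np.ndarray

    def __post_init__(self) -> None:
        self.cluster_labels = np.asarray(self.cluster_labels, dtype=object)
        if len(self.cluster_labels) != self.counts.n_cells:
            raise ValueError("cluster_labels length does not match cell count")
        if any(lab is None or str(lab) == "" for lab in self.cluster_labels):
            raise ValueError("every reference cell needs a non-empty label")
        if len(set(self.cluster_labels)) < 2:
            raise ValueError("reference must contain at least 2 distinct labels")

    @property
    def n_cells(self) -> int:
        return self.counts.n_cells


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_id_file(path: Path, what: str) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"{what} sidecar file missing: {path}")
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).to_numpy()
    return ids


def load_counts(path, fmt: Optional[str] = None) -> CountMatrix:
    """Read a count matrix from ``mtx``/``csv``/``tsv``.

    MatrixMarket files must be accompanied by ``genes.tsv`` and ``cells.tsv``
    sidecars in the same directory (one id per line). Delimited files carry
    gene ids in the header row and cell ids in the first column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "mtx":
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:  # re-raise with file context
            raise ValueError(f"malformed MatrixMarket file {path}: {exc}") from exc
        mat = sp.csr_matrix(mat)
        genes = _read_id_file(path.parent / "genes.tsv", "gene")
        cells = _read_id_file(path.parent / "cells.tsv", "cell")
        # stored orientation is cells x genes
        return CountMatrix(mat, cells, genes)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise ValueError(f"malformed {fmt} file {path}: {exc}") from exc
        return CountMatrix(
            df.to_numpy(dtype=float),
            df.index.astype(str).to_numpy(),
            df.columns.astype(str).to_numpy(),
        )
    raise ValueError(f"unknown count-matrix format: {fmt!r}")


def load_coords(path) -> pd.DataFrame:
    """Read a coordinates table with columns ``cell_id,x,y``."""
    df = pd.read_csv(path)
    required = {"cell_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinates file needs columns {sorted(required)}")
    return df


def load_labels(path) -> pd.DataFrame:
    """Read a labels table with columns ``cell_id,label``."""
    df = pd.read_csv(path)
    if not {"cell_id", "label"}.issubset(df.columns):
        raise ValueError("labels file needs columns ['cell_id', 'label']")
    return df


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_shared_genes(
    spatial: SpatialDataset,
    reference: ReferenceDataset,
    min_count: int = 5,
) -> tuple[SpatialDataset, ReferenceDataset]:
    """Restrict both modalities to shared genes and drop low-count cells.

    Genes are matched by exact case-sensitive id. The canonical output order
    is the reference gene order. Cells with total transcript count below
    ``min_count`` (default 5) are removed from each modality independently.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    sp_genes = set(spatial.counts.gene_ids)
    shared = [g for g in reference.counts.gene_ids if g in sp_genes]
    if not shared:
        raise ValueError("no shared genes between spatial and reference data")

    sp_counts = spatial.counts.subset_genes(shared)
    ref_counts = reference.counts.subset_genes(shared)

    keep_sp = sp_counts.cell_totals() >= min_count
    keep_ref = ref_counts.cell_totals() >= min_count
    if not keep_sp.any():
        raise ValueError("all spatial cells removed by the min_count filter")
    if not keep_ref.any():
        raise ValueError("all reference cells removed by the min_count filter")

    sp_out = SpatialDataset(
        sp_counts.subset_cells(keep_sp),
        spatial.coords[keep_sp],
        None if spatial.labels is None else spatial.labels[keep_sp],
    )
    ref_out = ReferenceDataset(
        ref_counts.subset_cells(keep_ref),
        reference.cluster_labels[keep_ref],
    )
    return sp_out, ref_out


# ---------------------------------------------------------------------------
# result-table export
# ---------------------------------------------------------------------------

def export_table(obj: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as delimited text, lossless to 1e-12.

    Floats are written with 17 significant digits so a read-back reproduces
    the values exactly. The delimiter follows the file suffix (``.tsv`` for
    tabs, comma otherwise).
    """
    if not isinstance(obj, pd.DataFrame):
        raise TypeError("export_table expects a pandas DataFrame result table")
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    try:
        obj.to_csv(path, sep=sep, index=index, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    return pd.read_csv(path, sep=sep)


def write_counts(counts: CountMatrix, path, fmt: Optional[str] = None) -> None:
    """Write a count matrix (inverse of :func:`load_counts`)."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "mtx":
        scipy.io.mmwrite(str(path), sp.coo_matrix(counts.values))
        pd.Series(counts.gene_ids).to_csv(path.parent / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(counts.cell_ids).to_csv(path.parent / "cells.tsv", sep="\t", header=False, index=False)
        return
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.DataFrame(counts.to_dense(), index=counts.cell_ids, columns=counts.gene_ids)
        df.to_csv(path, sep=sep, float_format="%.17g")
        return
    raise ValueError(f"unknown count-matrix format: {fmt!r}")
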