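"""Input/output, quality control and bipartite-graph construction.

The raw object of study is a cell-by-peak count matrix from a single-cell
ATAC-seq experiment: non-negative integer fragment counts over N cells and
M peaks (genomic intervals of recurrent accessibility, named "chr:start-end").
This module reads and writes that matrix in three plain dialects
(Matrix Market triplet + id files, dense TSV, HDF5 container), filters
low-quality cells and low-information peaks, computes per-cell library size
factors, binarizes counts into an incidence matrix R (r_ij = 1 iff x_ij > 0),
and assembles the symmetric-normalized adjacency of the cell-peak bipartite
graph that the encoder propagates over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "SizeFactors",
    "IncidenceMatrix",
    "BipartiteGraph",
    "load_matrix",
    "save_h5",
    "save_mtx",
    "qc_filter",
    "library_size_factors",
    "binarize",
    "build_bipartite",
]


@dataclass
class CountMatrix:
    """Cells-by-peaks accessibility counts with row/column identifiers.

    Cells are rows and peaks are columns everywhere in this package.
    Entries must be non-negative integers; ids must be unique.
    """

    counts: sp.csr_matrix
    cell_ids: list[str]
    peak_ids: list[str]
    cell_labels: np.ndarray | None = None
    batch_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n, m = self.counts.shape
        if n < 1 or m < 1:
            raise ValueError(f"empty matrix: shape {self.counts.shape}")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.peak_ids) != m:
            raise ValueError(f"{len(self.peak_ids)} peak ids for {m} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell ids are not unique")
        if len(set(self.peak_ids)) != m:
            raise ValueError("peak ids are not unique")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValueError("negative counts present")
            if not np.allclose(data, np.round(data)):
                raise ValueError("non-integer counts present")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)
        self.counts.eliminate_zeros()
        for name in ("cell_labels", "batch_labels"):
            lab = getattr(self, name)
            if lab is not None:
                lab = np.asarray(lab)
                if lab.shape[0] != n:
                    raise ValueError(f"{name} length {lab.shape[0]} != {n} cells")
                setattr(self, name, lab)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.counts.shape[1]


@dataclass
class SizeFactors:
    """Per-cell library size factors l_i (total count / median total)."""

    l: np.ndarray

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        if np.any(self.l <= 0):
            raise ValueError("size factors must be strictly positive")


@dataclass
class IncidenceMatrix:
    """Binary open/closed matrix R with r_ij = 1 iff the count is nonzero."""

    R: sp.csr_matrix

    def __post_init__(self) -> None:
        self.R = sp.csr_matrix(self.R)
        if self.R.data.size and not np.all(self.R.data == 1):
            raise ValueError("incidence matrix entries must be 0/1")


@dataclass
class BipartiteGraph:
    """Cell-peak bipartite graph with symmetric-normalized adjacency.

    ``norm_adjacency`` is the (N+M) x (N+M) matrix D^{-1/2} A D^{-1/2} where
    A = [[0, R], [R^T, 0]]; cell nodes come first, peak nodes after.
    """

    R: sp.csr_matrix
    cell_degrees: np.ndarray
    peak_degrees: np.ndarray
    norm_adjacency: sp.csr_matrix = field(repr=False)

    @property
    def n_cells(self) -> int:
        return self.R.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.R.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.R.shape[0] + self.R.shape[1]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FORMATS = ("mtx_triplet", "dense_tsv", "h5_container")


def load_matrix(path: str | Path, format: str) -> CountMatrix:
    """Read a count matrix; orientation is normalized to cells x peaks.

    ``mtx_triplet``: *path* is a directory containing ``matrix.mtx``,
    ``barcodes.tsv`` and ``peaks.tsv`` (one id per line). If the stored
    matrix is peaks x cells it is transposed using the id-file lengths.
    ``dense_tsv``: header row of peak ids, first column of cell ids.
    ``h5_container``: datasets /X/{data,indices,indptr,shape} (CSR),
    /obs/cell_id, /var/peak_id and optional /obs/cell_type, /obs/batch.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx_triplet":
        return _load_mtx(path)
    if format == "dense_tsv":
        return _load_dense_tsv(path)
    return _load_h5(path)


def _read_id_file(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip().split("\t")[0] for line in fh if line.strip()]


def _load_mtx(d: Path) -> CountMatrix:
    if not d.is_dir():
        raise FileNotFoundError(f"mtx_triplet expects a directory, got {d}")
    mat = sp.csr_matrix(scipy.io.mmread(d / "matrix.mtx"))
    cells = _read_id_file(d / "barcodes.tsv")
    peaks = _read_id_file(d / "peaks.tsv")
    n, m = mat.shape
    if (n, m) == (len(cells), len(peaks)):
        pass
    elif (m, n) == (len(cells), len(peaks)):
        mat = sp.csr_matrix(mat.T)
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither {len(cells)} barcodes "
            f"x {len(peaks)} peaks nor its transpose"
        )
    return CountMatrix(mat, cells, peaks)


def _load_dense_tsv(path: Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("empty matrix in dense TSV")
    return CountMatrix(
        sp.csr_matrix(df.to_numpy()),
        [str(c) for c in df.index],
        [str(p) for p in df.columns],
    )


def _load_h5(path: Path) -> CountMatrix:
    with h5py.File(path, "r") as f:
        x = f["X"]
        shape = tuple(x["shape"][:])
        mat = sp.csr_matrix(
            (x["data"][:], x["indices"][:], x["indptr"][:]), shape=shape
        )
        cells = [s.decode() for s in f["obs/cell_id"][:]]
        peaks = [s.decode() for s in f["var/peak_id"][:]]
        labels = None
        batches = None
        if "obs/cell_type" in f:
            labels = np.array([s.decode() for s in f["obs/cell_type"][:]])
        if "obs/batch" in f:
            batches = np.array([s.decode() for s in f["obs/batch"][:]])
    return CountMatrix(mat, cells, peaks, labels, batches)


def save_h5(x: CountMatrix, path: str | Path) -> None:
    """Write a CountMatrix to the package's HDF5 container layout."""
    x.counts.sort_indices()
    with h5py.File(path, "w") as f:
        g = f.create_group("X")
        g.create_dataset("data", data=x.counts.data)
        g.create_dataset("indices", data=x.counts.indices)
        g.create_dataset("indptr", data=x.counts.indptr)
        g.create_dataset("shape", data=np.array(x.counts.shape))
        f.create_group("obs").create_dataset(
            "cell_id", data=np.array(x.cell_ids, dtype="S")
        )
        f.create_group("var").create_dataset(
            "peak_id", data=np.array(x.peak_ids, dtype="S")
        )
        if x.cell_labels is not None:
            f["obs"].create_dataset(
                "cell_type", data=np.array(x.cell_labels, dtype="S")
            )
        if x.batch_labels is not None:
            f["obs"].create_dataset("batch", data=np.array(x.batch_labels, dtype="S"))


def save_mtx(x: CountMatrix, d: str | Path) -> None:
    """Write matrix.mtx + barcodes.tsv + peaks.tsv into directory *d*."""
    d = Path(d)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(d / "matrix.mtx"), sp.coo_matrix(x.counts))
    (d / "barcodes.tsv").write_text("\n".join(x.cell_ids) + "\n")
    (d / "peaks.tsv").write_text("\n".join(x.peak_ids) + "\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def qc_filter(
    x: CountMatrix, min_peaks_per_cell: int = 100, min_cells_per_peak: int = 3
) -> CountMatrix:
    """Drop low-quality cells, then low-information peaks, in one pass.

    Cells must have at least ``min_peaks_per_cell`` nonzero peaks; afterwards
    peaks must be nonzero in at least ``min_cells_per_peak`` of the surviving
    cells. Defaults are common community choices.
    """
    if min_peaks_per_cell < 1 or min_cells_per_peak < 1:
        raise ValueError("QC thresholds must be >= 1")
    nz_per_cell = np.diff(x.counts.indptr)
    keep_cells = nz_per_cell >= min_peaks_per_cell
    if not keep_cells.any():
        raise ValueError(
            "all cells removed by QC; lower min_peaks_per_cell "
            f"(currently {min_peaks_per_cell})"
        )
    sub = x.counts[keep_cells]
    nz_per_peak = np.asarray((sub > 0).sum(axis=0)).ravel()
    keep_peaks = nz_per_peak >= min_cells_per_peak
    if not keep_peaks.any():
        raise ValueError(
            "all peaks removed by QC; lower min_cells_per_peak "
            f"(currently {min_cells_per_peak})"
        )
    cell_idx = np.flatnonzero(keep_cells)
    peak_idx = np.flatnonzero(keep_peaks)
    return CountMatrix(
        sub[:, keep_peaks],
        [x.cell_ids[i] for i in cell_idx],
        [x.peak_ids[j] for j in peak_idx],
        None if x.cell_labels is None else x.cell_labels[cell_idx],
        None if x.batch_labels is None else x.batch_labels[cell_idx],
    )


def library_size_factors(x: CountMatrix) -> SizeFactors:
    """l_i = (total count of cell i) / (median total count across cells)."""
    totals = np.asarray(x.counts.sum(axis=1), dtype=float).ravel()
    if np.any(totals <= 0):
        raise ValueError("cells with zero total count; run qc_filter first")
    med = float(np.median(totals))
    if med <= 0:
        raise ValueError("median library size is zero")
    return SizeFactors(totals / med)


def binarize(x: CountMatrix) -> IncidenceMatrix:
    """R with r_ij = 1 exactly where the count is positive."""
    r = x.counts.copy()
    r.data = np.ones_like(r.data)
    return IncidenceMatrix(sp.csr_matrix(r, dtype=np.float64))


def build_bipartite(r: IncidenceMatrix) -> BipartiteGraph:
    """Assemble D^{-1/2} A D^{-1/2} for A = [[0, R], [R^T, 0]].

    Edge (cell i, peak j) gets weight 1/sqrt(|N_c(i)| |N_p(j)|) where the
    degrees are the row/column sums of R. Every node must have degree >= 1.
    """
    R = r.R
    cell_deg = np.asarray(R.sum(axis=1), dtype=float).ravel()
    peak_deg = np.asarray(R.sum(axis=0), dtype=float).ravel()
    if np.any(cell_deg == 0) or np.any(peak_deg == 0):
        raise ValueError(
            "degree-0 node in incidence matrix; apply qc_filter before "
            "building the bipartite graph"
        )
    d_c = sp.diags(1.0 / np.sqrt(cell_deg))
    d_p = sp.diags(1.0 / np.sqrt(peak_deg))
    rn = sp.csr_matrix(d_c @ R @ d_p)
    n, m = R.shape
    adj = sp.bmat([[None, rn], [rn.T, None]], format="csr", dtype=np.float64)
    assert adj.shape == (n + m, n + m)
    return BipartiteGraph(R=R, cell_degrees=cell_deg, peak_degrees=peak_deg,
                          norm_adjacency=adj)
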