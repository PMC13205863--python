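"""Ground-truthed synthetic scATAC-seq data.

Two generation modes:

* **block mode** — a fully synthetic matrix with explicit cluster-specific
  cell-peak structure: cells and peaks are partitioned into groups, an entry
  is open with probability ``p_in`` when the cell's and peak's groups match
  and ``p_out`` otherwise, and open entries carry 1 + Poisson(mean_count)
  fragments. Dropout is then applied by masking observed entries to zero.

* **bulk-guided mode** — counts in {0, 1, 2} per peak and cell (the diploid
  setting), drawn c_ij ~ Binomial(2, p_it) where the success probability
  mixes a bulk-derived peak prevalence with a uniform-noise component:

      p_it = (n/2) * [ r_it * (1 - q) + q / k ]

  with depth n (fragments per cell), noise q in [0, 1] and k peaks. Under
  this form the expected total count per cell is exactly n for any q, the
  q -> 0 limit is governed purely by the bulk prevalence r_it, and q -> 1
  spreads fragments uniformly across peaks. p_it can exceed 1 at high depth
  for dominant peaks; such entries are clamped to 1 with a logged count.

No external bulk reference ships with the package: a synthetic per-type
prevalence matrix with Dirichlet-tilted block enrichment stands in for it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import scipy.sparse as sp

from .io_preprocess import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimSpec",
    "Prevalence",
    "SimTruth",
    "simulate_block",
    "apply_dropout",
    "prevalence_from_counts",
    "synthetic_bulk_prevalence",
    "simulate_cells",
    "simulation_grid",
]


@dataclass
class SimSpec:
    """Settings for one bulk-guided simulation."""

    n_cells_per_type: int
    cell_types: list[str]
    n_peaks: int
    depth: int
    noise: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 1 or self.depth < 1:
            raise ValueError("n_peaks and depth must be >= 1")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must lie in [0, 1]")


@dataclass
class Prevalence:
    """k x T per-type peak rates; each column sums to 1."""

    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if np.any(self.r < 0):
            raise ValueError("prevalence entries must be >= 0")
        sums = self.r.sum(axis=0)
        if not np.allclose(sums, 1.0):
            raise ValueError("prevalence columns must sum to 1")


@dataclass
class SimTruth:
    """Simulated counts with full ground truth.

    ``reference`` is the noiseless signal: the per-cell Binomial success
    probabilities in bulk-guided mode, or the pre-dropout counts in block
    mode. ``mask`` records the (row, col) positions zeroed by dropout.
    """

    counts: CountMatrix
    labels: np.ndarray
    reference: np.ndarray | sp.spmatrix
    mask: tuple[np.ndarray, np.ndarray] = field(
        default_factory=lambda: (np.array([], dtype=int), np.array([], dtype=int))
    )
    provenance: dict = field(default_factory=dict)


def _group_sizes(total: int, n_groups: int) -> np.ndarray:
    """Even partition; remainder goes to the last group."""
    base = total // n_groups
    sizes = np.full(n_groups, base)
    sizes[-1] += total - base * n_groups
    return sizes


def simulate_block(
    n_cells: int,
    n_peaks: int,
    n_groups: int,
    p_in: float,
    p_out: float,
    mean_count: float = 1.0,
    seed: int = 0,
) -> SimTruth:
    """Block-structured matrix: within-group entries open at p_in, others p_out."""
    if n_groups > n_cells or n_groups > n_peaks:
        raise ValueError("more groups than cells or peaks")
    if not p_in > p_out:
        raise ValueError("p_in must exceed p_out")
    rng = np.random.default_rng(seed)
    cell_groups = np.repeat(np.arange(n_groups), _group_sizes(n_cells, n_groups))
    peak_groups = np.repeat(np.arange(n_groups), _group_sizes(n_peaks, n_groups))
    same = cell_groups[:, None] == peak_groups[None, :]
    p = np.where(same, p_in, p_out)
    open_mask = rng.random((n_cells, n_peaks)) < p
    counts = np.zeros((n_cells, n_peaks), dtype=np.int64)
    counts[open_mask] = 1 + rng.poisson(mean_count, size=int(open_mask.sum()))
    labels = np.array([f"group{g}" for g in cell_groups])
    cm = CountMatrix(
        sp.csr_matrix(counts),
        [f"cell{i}" for i in range(n_cells)],
        [f"chr1:{1000 * j}-{1000 * j + 500}" for j in range(n_peaks)],
        cell_labels=labels,
    )
    return SimTruth(
        counts=cm,
        labels=labels,
        reference=sp.csr_matrix(counts),
        provenance={
            "mode": "block", "n_cells": n_cells, "n_peaks": n_peaks,
            "n_groups": n_groups, "p_in": p_in, "p_out": p_out,
            "mean_count": mean_count, "seed": seed,
            "peak_groups": peak_groups,
        },
    )


def apply_dropout(x: CountMatrix, rate: float, seed: int = 0) -> SimTruth:
    """Zero each nonzero entry independently with the given probability.

    Returns the thinned counts together with the mask of zeroed positions;
    original zeros are untouched, so nnz(after) + |mask| = nnz(before).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    coo = x.counts.tocoo()
    drop = rng.random(coo.nnz) < rate
    kept = sp.coo_matrix(
        (coo.data[~drop], (coo.row[~drop], coo.col[~drop])), shape=coo.shape
    ).tocsr()
    cm = CountMatrix(kept, list(x.cell_ids), list(x.peak_ids),
                     x.cell_labels, x.batch_labels)
    return SimTruth(
        counts=cm,
        labels=x.cell_labels if x.cell_labels is not None else np.array([]),
        reference=x.counts.copy(),
        mask=(coo.row[drop].copy(), coo.col[drop].copy()),
        provenance={"mode": "dropout", "rate": rate, "seed": seed},
    )


def prevalence_from_counts(bulk: np.ndarray) -> Prevalence:
    """Column-normalize a k x T bulk count matrix into per-type peak rates."""
    bulk = np.asarray(bulk, dtype=float)
    totals = bulk.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("bulk column with zero total reads")
    return Prevalence(bulk / totals)


def synthetic_bulk_prevalence(
    n_peaks: int, n_types: int, enrichment: float = 5.0, seed: int = 0
) -> Prevalence:
    """Stand-in bulk prevalence with block structure (synthetic).

    Peaks are partitioned into ``n_types`` blocks; each type's rate vector is
    a Dirichlet draw whose concentration is tilted by ``enrichment`` on its
    own block, giving per-type enriched peaks like a sorted-population bulk
    profile would.
    """
    rng = np.random.default_rng(seed)
    peak_groups = np.repeat(np.arange(n_types), _group_sizes(n_peaks, n_types))
    r = np.empty((n_peaks, n_types))
    for t in range(n_types):
        alpha = np.where(peak_groups == t, 1.0 + enrichment, 1.0)
        r[:, t] = rng.dirichlet(alpha)
    return Prevalence(r)


def simulate_cells(r: Prevalence, spec: SimSpec) -> SimTruth:
    """Draw c_ij ~ Binomial(2, p_it) for every cell j of type t and peak i.

    p_it = (depth/2) * [r_it (1-q) + q/k], clamped at 1 with a logged count
    of clamped entries. Returns counts (cells x peaks, values in {0,1,2}),
    type labels, and the per-cell success-probability matrix as reference.
    """
    k, n_types = r.r.shape
    if k != spec.n_peaks:
        raise ValueError(f"prevalence has {k} peaks, spec says {spec.n_peaks}")
    if n_types != len(spec.cell_types):
        raise ValueError("prevalence columns != number of cell types")
    q, depth = spec.noise, spec.depth
    p = 0.5 * depth * (r.r * (1.0 - q) + q / k)  # k x T
    n_over = int((p > 1.0).sum())
    if n_over:
        if n_over == p.size:
            raise ValueError("every p_it exceeds 1; reduce depth")
        logger.warning("clamping %d of %d success probabilities to 1",
                       n_over, p.size)
        p = np.minimum(p, 1.0)
    rng = np.random.default_rng(spec.seed)
    n_cells = spec.n_cells_per_type * n_types
    counts = np.empty((n_cells, k), dtype=np.int64)
    labels = np.empty(n_cells, dtype=object)
    ref = np.empty((n_cells, k))
    row = 0
    for t, name in enumerate(spec.cell_types):
        for _ in range(spec.n_cells_per_type):
            counts[row] = rng.binomial(2, p[:, t])
            labels[row] = name
            ref[row] = p[:, t]
            row += 1
    labels = labels.astype(str)
    cm = CountMatrix(
        sp.csr_matrix(counts),
        [f"cell{i}" for i in range(n_cells)],
        [f"chr1:{1000 * j}-{1000 * j + 500}" for j in range(k)],
        cell_labels=labels,
    )
    return SimTruth(
        counts=cm, labels=labels, reference=ref,
        provenance={"mode": "bulk", "depth": depth, "noise": q,
                    "seed": spec.seed, "n_clamped": n_over},
    )


def simulation_grid(
    depths: list[int], noises: list[float], base: SimSpec,
    r: Prevalence | None = None,
) -> list[SimTruth]:
    """Cartesian product over depth and noise settings, seeds varied per cell.

    The published grid uses depths {1000..5000} and noise {0.2, 0.3, 0.4}.
    """
    if not depths or not noises:
        raise ValueError("depth and noise lists must be non-empty")
    if r is None:
        r = synthetic_bulk_prevalence(base.n_peaks, len(base.cell_types),
                                      seed=base.seed)
    out = []
    for idx, (depth, q) in enumerate(product(depths, noises)):
        spec = SimSpec(
            n_cells_per_type=base.n_cells_per_type,
            cell_types=list(base.cell_types),
            n_peaks=base.n_peaks,
            depth=int(depth),
            noise=float(q),
            seed=base.seed + 1 + idx,
        )
        truth = simulate_cells(r, spec)
        truth.provenance["grid_index"] = idx
        out.append(truth)
    return out
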