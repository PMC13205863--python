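"""Evaluation metrics for imputation quality, clustering and integration.

Imputation agreement: Pearson correlation (summarized cell-wise and
peak-wise), auROC and auPRC against the binarized ground truth. Clustering
agreement: ARI, NMI (arithmetic-mean normalization), homogeneity,
completeness and V-measure. Integration/mixing: cell-type ASW rescaled to
[0,1], batch ASW (1 - |silhouette| within each cell-type group), cLISI and
iLISI (rescaled median inverse Simpson indices over kNN neighborhoods),
kBET acceptance rate (chi-square test of local vs global batch
composition), and graph connectivity (mean largest-connected-component
fraction of each label's induced kNN subgraph).

Partition metrics, silhouettes and ROC/PR areas delegate to scikit-learn;
LISI, kBET, batch ASW, graph connectivity and the weighted V-measure are
implemented here directly. Entropic quantities use natural logarithms and
the 0*log0 = 0 convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import chisquare
from sklearn.metrics import (
    adjusted_rand_score,
    average_precision_score,
    homogeneity_score,
    completeness_score,
    normalized_mutual_info_score,
    roc_auc_score,
    silhouette_samples,
    silhouette_score,
)
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledEmbedding", "MetricReport", "pcc", "pcc_matrix", "auroc_auprc",
    "ari", "nmi", "homogeneity_completeness", "v_measure", "asw_celltype",
    "asw_batch", "lisi", "kbet_accept", "graph_connectivity",
]


@dataclass
class LabeledEmbedding:
    """An N x d embedding with cell-type labels and optional batch labels."""

    coords: np.ndarray
    labels: np.ndarray
    batches: np.ndarray | None = None
    knn_k: int = 15

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.coords.ndim != 2 or self.coords.shape[0] < 2:
            raise ValueError("coords must be N x d with N >= 2")
        if self.labels.shape[0] != self.coords.shape[0]:
            raise ValueError("labels length != number of points")
        if self.batches is not None:
            self.batches = np.asarray(self.batches)
            if self.batches.shape[0] != self.coords.shape[0]:
                raise ValueError("batches length != number of points")


@dataclass
class MetricReport:
    """Named scalar results of one evaluation run (None = not computed)."""

    pcc_cellwise: float | None = None
    pcc_peakwise: float | None = None
    auroc: float | None = None
    auprc: float | None = None
    ari: float | None = None
    nmi: float | None = None
    homogeneity: float | None = None
    completeness: float | None = None
    v_measure: float | None = None
    asw_celltype: float | None = None
    asw_batch: float | None = None
    clisi: float | None = None
    ilisi: float | None = None
    kbet_accept: float | None = None
    graph_connectivity: float | None = None

    def to_dict(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


# ---------------------------------------------------------------------------
# correlation / ranking
# ---------------------------------------------------------------------------

def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; errors on zero-variance input (undefined)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    xd, yd = x - x.mean(), y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        raise ValueError("zero-variance input; correlation undefined")
    return float((xd * yd).sum() / denom)


def pcc_matrix(a: np.ndarray, b: np.ndarray, axis: str = "cellwise") -> float:
    """Mean per-row (cellwise) or per-column (peakwise) Pearson correlation.

    Slices where either matrix has zero variance are skipped with a logged
    count; errors if nothing remains.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must share shape")
    if axis not in ("cellwise", "peakwise"):
        raise ValueError("axis must be 'cellwise' or 'peakwise'")
    if axis == "peakwise":
        a, b = a.T, b.T
    ad = a - a.mean(axis=1, keepdims=True)
    bd = b - b.mean(axis=1, keepdims=True)
    va = (ad**2).sum(axis=1)
    vb = (bd**2).sum(axis=1)
    ok = (va > 0) & (vb > 0)
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info("pcc_matrix: skipped %d zero-variance slices", n_skip)
    if not ok.any():
        raise ValueError("all slices have zero variance")
    r = (ad[ok] * bd[ok]).sum(axis=1) / np.sqrt(va[ok] * vb[ok])
    return float(r.mean())


def auroc_auprc(scores: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """ROC and precision-recall areas of scores against a binary truth."""
    truth = np.asarray(truth).astype(int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if len(np.unique(truth)) < 2:
        raise ValueError("truth must contain both classes")
    return (
        float(roc_auc_score(truth, scores)),
        float(average_precision_score(truth, scores)),
    )


# ---------------------------------------------------------------------------
# partition agreement
# ---------------------------------------------------------------------------

def _check_lengths(a, b) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("labelings have different lengths")
    return a, b


def ari(a, b) -> float:
    """Adjusted Rand index: 1 = identical partitions, ~0 = random."""
    a, b = _check_lengths(a, b)
    return float(adjusted_rand_score(a, b))


def nmi(a, b) -> float:
    """Mutual information normalized by the arithmetic mean of the entropies."""
    a, b = _check_lengths(a, b)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def homogeneity_completeness(truth, pred) -> tuple[float, float]:
    """h = 1 - H(C|K)/H(C), c = 1 - H(K|C)/H(K); 0/0 cases return 1."""
    truth, pred = _check_lengths(truth, pred)
    return (
        float(homogeneity_score(truth, pred)),
        float(completeness_score(truth, pred)),
    )


def v_measure(h: float, c: float, weight: float = 1.0) -> float:
    """Weighted harmonic mean (1+beta) h c / (beta h + c); 0 when h = c = 0."""
    tol = 1e-9  # tolerate float round-off from upstream entropy ratios
    if not (-tol <= h <= 1.0 + tol and -tol <= c <= 1.0 + tol):
        raise ValueError("h and c must lie in [0, 1]")
    h = min(max(h, 0.0), 1.0)
    c = min(max(c, 0.0), 1.0)
    if weight <= 0:
        raise ValueError("weight must be positive")
    if h == 0.0 and c == 0.0:
        return 0.0
    return float((1.0 + weight) * h * c / (weight * h + c))


# ---------------------------------------------------------------------------
# embedding-space metrics
# ---------------------------------------------------------------------------

def asw_celltype(e: LabeledEmbedding) -> float:
    """(mean silhouette width + 1) / 2 on the cell-type partition."""
    if len(np.unique(e.labels)) < 2:
        raise ValueError("cell-type ASW needs >= 2 labels")
    s = silhouette_score(e.coords, e.labels, metric="euclidean")
    return float((s + 1.0) / 2.0)


def asw_batch(e: LabeledEmbedding) -> float:
    """Mean over cell-type groups of mean(1 - |batch silhouette|) within group.

    A score near 1 means batches are well mixed inside every cell type.
    Groups containing fewer than 2 batches (or too few cells to define a
    silhouette) are skipped with a log message.
    """
    if e.batches is None:
        raise ValueError("batch labels required")
    scores = []
    for lab in np.unique(e.labels):
        idx = e.labels == lab
        sub_batches = e.batches[idx]
        uniq = np.unique(sub_batches)
        if len(uniq) < 2 or idx.sum() <= len(uniq):
            logger.info("asw_batch: skipping group %r (insufficient batches)", lab)
            continue
        s = silhouette_samples(e.coords[idx], sub_batches, metric="euclidean")
        scores.append(float(np.mean(1.0 - np.abs(s))))
    if not scores:
        raise ValueError("no cell-type group with >= 2 batches")
    return float(np.mean(scores))


def _knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbors of each point, self excluded."""
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    # kneighbors with no query set excludes each point from its own neighbors
    return nn.kneighbors(return_distance=False)


def lisi(e: LabeledEmbedding, on: str = "label") -> float:
    """Rescaled median inverse Simpson index over kNN neighborhoods.

    Raw per-cell LISI is 1 / sum_b p_b^2 over the categorical composition of
    the cell's k nearest neighbors (1 = single category, B = uniform mix).
    The median across cells is mapped to [0, 1]: labels use
    f(x) = (B - x)/(B - 1) (cLISI, 1 = well-separated types) and batches use
    g(x) = (x - 1)/(B - 1) (iLISI, 1 = well-mixed batches).
    """
    if on not in ("label", "batch"):
        raise ValueError("on must be 'label' or 'batch'")
    cats = e.labels if on == "label" else e.batches
    if cats is None:
        raise ValueError("batch labels required for iLISI")
    n = e.coords.shape[0]
    if e.knn_k >= n:
        raise ValueError(f"knn_k={e.knn_k} must be < N={n}")
    uniq, codes = np.unique(cats, return_inverse=True)
    b = len(uniq)
    if b < 2:
        raise ValueError("need >= 2 categories")
    idx = _knn_indices(e.coords, e.knn_k)
    neigh = codes[idx]  # (N, k)
    simpson = np.zeros(n)
    for c in range(b):
        p = (neigh == c).mean(axis=1)
        simpson += p**2
    raw = 1.0 / simpson
    med = float(np.median(raw))
    if on == "label":
        return (b - med) / (b - 1)
    return (med - 1.0) / (b - 1)


def kbet_accept(
    e: LabeledEmbedding,
    n_samples: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of sampled neighborhoods whose batch mix passes a chi-square test.

    For each sampled cell, the batch composition of its k nearest neighbors
    is tested against the global batch frequencies (goodness of fit,
    dof = #batches - 1 after merging). Batches whose expected neighborhood
    count falls below 1 are merged smallest-first, per standard chi-square
    practice. Returns the acceptance rate (p > alpha) in [0, 1].
    """
    if e.batches is None:
        raise ValueError("batch labels required")
    uniq, codes = np.unique(e.batches, return_inverse=True)
    b = len(uniq)
    if b < 2:
        raise ValueError("kBET needs >= 2 batches")
    if e.knn_k < b:
        raise ValueError("knn_k must be >= number of batches")
    n = e.coords.shape[0]
    global_freq = np.bincount(codes, minlength=b) / n
    expected = e.knn_k * global_freq

    order = np.argsort(expected)
    merged_groups: list[list[int]] = []
    acc: list[int] = []
    acc_exp = 0.0
    for bi in order:
        acc.append(int(bi))
        acc_exp += expected[bi]
        if acc_exp >= 1.0:
            merged_groups.append(acc)
            acc, acc_exp = [], 0.0
    if acc:
        if merged_groups:
            merged_groups[-1].extend(acc)
        else:
            raise ValueError("total expected neighborhood count < 1; increase knn_k")
    if len(merged_groups) < b:
        logger.info("kbet: merged %d batches into %d groups",
                    b, len(merged_groups))
    if len(merged_groups) < 2:
        raise ValueError("fewer than 2 batch groups after merging")
    group_of = np.empty(b, dtype=int)
    for gi, grp in enumerate(merged_groups):
        group_of[grp] = gi
    gcodes = group_of[codes]
    g = len(merged_groups)
    gfreq = np.bincount(gcodes, minlength=g) / n

    rng = np.random.default_rng(seed)
    sample = rng.choice(n, size=min(n_samples, n), replace=False)
    idx = _knn_indices(e.coords, e.knn_k)
    accept = 0
    for i in sample:
        obs = np.bincount(gcodes[idx[i]], minlength=g)
        stat = chisquare(obs, f_exp=e.knn_k * gfreq)
        if stat.pvalue > alpha:
            accept += 1
    return accept / len(sample)


def graph_connectivity(e: LabeledEmbedding) -> float:
    """Mean over labels of |largest connected component| / |label subgraph|.

    The kNN graph is symmetrized by edge union; 1 means every group of
    same-labeled cells stays connected in the embedding.
    """
    n = e.coords.shape[0]
    k = min(e.knn_k, n - 1)
    idx = _knn_indices(e.coords, k)
    rows = np.repeat(np.arange(n), k)
    adj = sp.coo_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    ).tocsr()
    adj = ((adj + adj.T) > 0).astype(np.int8)
    scores = []
    for lab in np.unique(e.labels):
        members = np.flatnonzero(e.labels == lab)
        if members.size == 0:
            logger.info("graph_connectivity: empty label %r skipped", lab)
            continue
        if members.size == 1:
            scores.append(1.0)
            continue
        sub = adj[members][:, members]
        n_comp, comp = connected_components(sub, directed=False)
        largest = np.bincount(comp).max()
        scores.append(largest / members.size)
    return float(np.mean(scores))
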