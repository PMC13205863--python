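"""Downstream regulatory analysis on learned peak embeddings.

Peaks that share regulatory context end up close in embedding space, so a
cosine kNN graph over peak embeddings plus Leiden community detection
yields discrete peak modules. Module activity in a cell is the fraction of
the module's peaks accessible in that cell (computed on the binarized
QC-filtered matrix, not the imputed one), summarized per cell type as a
z-scored heatmap matrix. An anchor peak's regulatory neighborhood is read
out by ranking all other peaks by cosine similarity of their embeddings;
promoter-annotated hits map to a deduplicated gene shortlist.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .io_preprocess import IncidenceMatrix

__all__ = [
    "PeakModuleAssignment", "ModuleActivity", "peak_knn_graph",
    "detect_modules", "module_activity", "celltype_module_matrix",
    "coaccessibility_rank", "anchor_gene_shortlist",
]


@dataclass
class PeakModuleAssignment:
    """One module id per peak, plus the graph and resolution that made it."""

    module_id: np.ndarray
    graph: igraph.Graph
    resolution: float

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.module_id))


@dataclass
class ModuleActivity:
    """Cells x modules activity fractions in [0, 1]."""

    scores: np.ndarray
    module_labels: np.ndarray


def _knn_edges_cosine(x: np.ndarray, k: int) -> np.ndarray:
    """Union-symmetrized cosine kNN edge list (no self edges)."""
    nn = NearestNeighbors(n_neighbors=k, metric="cosine").fit(x)
    # kneighbors with no query set excludes each point from its own neighbors
    idx = nn.kneighbors(return_distance=False)
    n = x.shape[0]
    src = np.repeat(np.arange(n), idx.shape[1])
    dst = idx.ravel()
    keep = src != dst
    pairs = np.sort(np.column_stack([src[keep], dst[keep]]), axis=1)
    return np.unique(pairs, axis=0)


def peak_knn_graph(zp: np.ndarray, k: int = 30) -> igraph.Graph:
    """Cosine-distance kNN graph among peaks, symmetrized by edge union."""
    zp = np.asarray(zp, dtype=float)
    if k >= zp.shape[0]:
        raise ValueError(f"k={k} must be < number of peaks {zp.shape[0]}")
    norms = np.linalg.norm(zp, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"zero-norm embedding for peak index {int(bad[0])}")
    edges = _knn_edges_cosine(zp, k)
    g = igraph.Graph(n=zp.shape[0], edges=[tuple(e) for e in edges])
    return g


def detect_modules(
    graph: igraph.Graph, resolution: float = 1.0, seed: int = 0
) -> PeakModuleAssignment:
    """Leiden community detection at the given resolution (deterministic per seed)."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return PeakModuleAssignment(
        module_id=np.asarray(part.membership), graph=graph, resolution=resolution
    )


def module_activity(r: IncidenceMatrix, a: PeakModuleAssignment) -> ModuleActivity:
    """Fraction of each module's peaks open per cell: (R @ onehot) / sizes."""
    modules = np.unique(a.module_id)
    m = r.R.shape[1]
    if a.module_id.shape[0] != m:
        raise ValueError("module assignment length != number of peaks")
    onehot = sp.csr_matrix(
        (np.ones(m), (np.arange(m), np.searchsorted(modules, a.module_id))),
        shape=(m, modules.size),
    )
    sizes = np.asarray(onehot.sum(axis=0)).ravel()
    if np.any(sizes == 0):
        raise ValueError("empty module")
    scores = np.asarray((r.R @ onehot).todense()) / sizes
    return ModuleActivity(scores=scores, module_labels=modules)


def celltype_module_matrix(
    scores: ModuleActivity, labels: np.ndarray, eps: float = 1e-8
) -> np.ndarray:
    """Per-type mean activity, z-scored per module across types (sd + eps)."""
    labels = np.asarray(labels)
    types = np.unique(labels)
    if types.size < 2:
        raise ValueError("need >= 2 cell types")
    means = np.vstack([scores.scores[labels == t].mean(axis=0) for t in types])
    mu = means.mean(axis=0)
    sd = means.std(axis=0)
    return (means - mu) / (sd + eps)


def coaccessibility_rank(
    zp: np.ndarray, peak_ids: list[str], anchor: str, top_n: int = 100
) -> list[tuple[str, float]]:
    """Peaks ranked by cosine similarity of embedding to the anchor peak.

    The anchor itself is excluded; at most top_n entries are returned.
    """
    try:
        ai = peak_ids.index(anchor)
    except ValueError:
        raise KeyError(f"unknown anchor peak {anchor!r}") from None
    zp = np.asarray(zp, dtype=float)
    norms = np.linalg.norm(zp, axis=1)
    sims = (zp @ zp[ai]) / np.maximum(norms * norms[ai], 1e-300)
    order = [j for j in np.argsort(-sims) if j != ai][:top_n]
    return [(peak_ids[j], float(sims[j])) for j in order]


def anchor_gene_shortlist(
    ranking: list[tuple[str, float]],
    peak2gene: dict[str, str],
    top_k: int = 100,
) -> list[str]:
    """Genes of promoter peaks in ranking order, deduplicated at best rank."""
    if not peak2gene:
        raise ValueError("empty peak-to-gene mapping")
    seen: dict[str, None] = {}
    for peak, _ in ranking:
        gene = peak2gene.get(peak)
        if gene is not None and gene not in seen:
            seen[gene] = None
    return list(seen)[:top_k]
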