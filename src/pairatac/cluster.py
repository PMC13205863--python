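"""Leiden clustering of an embedding via a symmetrized Euclidean kNN graph.

This is the clustering protocol used when evaluating embeddings against
known cell groups: build a k-nearest-neighbor graph (k = 15 by default,
Euclidean, union-symmetrized) and partition it with Leiden at a given
resolution. Deterministic given the seed.
"""

from __future__ import annotations

import igraph
import leidenalg
import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["leiden_cluster"]


def leiden_cluster(
    coords: np.ndarray, k: int = 15, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < N={n}")
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    # kneighbors with no query set excludes each point from its own neighbors
    idx = nn.kneighbors(return_distance=False)
    src = np.repeat(np.arange(n), idx.shape[1])
    dst = idx.ravel()
    keep = src != dst
    pairs = np.sort(np.column_stack([src[keep], dst[keep]]), axis=1)
    edges = np.unique(pairs, axis=0)
    g = igraph.Graph(n=n, edges=[tuple(e) for e in edges])
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)
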