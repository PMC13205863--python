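"""Bipartite message-passing encoder.

The encoder is deliberately linear: trainable 0-th-layer ID embeddings for
every cell and peak node, propagated K times by the symmetric-normalized
adjacency E^(k+1) = D^{-1/2} A D^{-1/2} E^(k) — no nonlinearity, no feature
transform, no self-loops — and read out by combining the K+1 layers. One
propagation moves information across the cell-peak edges; two recover
cell-cell similarity through shared peaks and peak-peak co-accessibility
through shared cells.
"""

from __future__ import annotations

import numpy as np

from .io_preprocess import BipartiteGraph

__all__ = ["init_embeddings", "propagate", "layer_stack", "readout", "encode"]

_READOUTS = ("mean", "sum", "concat")


def init_embeddings(
    n_nodes: int, dim: int, init_std: float = 0.1, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Seeded i.i.d. normal init of E^(0); small scale keeps initial logits near 0."""
    rng = np.random.default_rng(rng)
    return rng.normal(0.0, init_std, size=(n_nodes, dim))


def propagate(e: np.ndarray, g: BipartiteGraph) -> np.ndarray:
    """One round of normalized neighborhood aggregation: Â e."""
    e = np.asarray(e)
    if e.shape[0] != g.n_nodes:
        raise ValueError(f"embedding has {e.shape[0]} rows, graph has {g.n_nodes} nodes")
    return g.norm_adjacency @ e


def layer_stack(e0: np.ndarray, g: BipartiteGraph, n_layers: int) -> list[np.ndarray]:
    """[E^(0), Â E^(0), ..., Â^K E^(0)]."""
    if n_layers < 0:
        raise ValueError("n_layers must be >= 0")
    layers = [np.asarray(e0)]
    for _ in range(n_layers):
        layers.append(propagate(layers[-1], g))
    return layers


def readout(stack: list[np.ndarray], mode: str = "mean") -> np.ndarray:
    """Combine the propagation layers into the final embedding Ē.

    ``mean`` (default) weights every neighborhood order equally and keeps the
    0-th layer's self-information in the mix; ``sum`` and ``concat`` are
    provided as configurable alternatives.
    """
    if not stack:
        raise ValueError("empty layer stack")
    if mode not in _READOUTS:
        raise ValueError(f"unknown readout {mode!r}; expected one of {_READOUTS}")
    if mode == "mean":
        return np.mean(stack, axis=0)
    if mode == "sum":
        return np.sum(stack, axis=0)
    return np.concatenate(stack, axis=1)


def encode(e0: np.ndarray, g: BipartiteGraph, n_layers: int, mode: str = "mean") -> np.ndarray:
    """Full encoder: propagate K times and read out."""
    return readout(layer_stack(e0, g, n_layers), mode)
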