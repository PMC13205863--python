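"""Dual decoders: pairwise-ranking edge reconstruction and NB count model.

The qualitative decoder scores a cell-peak pair by the inner product of
their latent embeddings, h_ij = z_i^(c) . z_j^(p), interpreted through a
logistic link as the probability the peak is open in the cell. Because the
incidence matrix is extremely sparse, it is trained with negative sampling
and a Bayesian-personalized-ranking loss -ln sigma(h+ - h-): observed open
peaks should outrank sampled closed peaks.

The quantitative decoder reconstructs counts with a Negative Binomial
likelihood. The NB mean mu'_ij = l_i * s_j * softplus(w . (z_c ⊙ z_p) + b)
combines the cell's library size factor l_i, a learnable positive per-peak
factor s_j, and a latent interaction intensity; the per-peak
inverse-dispersion theta_j = softplus(u_j) gives Var = mu' + mu'^2 / theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

from .io_preprocess import IncidenceMatrix
from .variational_latent import LatentSample, softplus

__all__ = [
    "QuantHead",
    "edge_score",
    "bpr_loss",
    "sample_negatives",
    "nb_mean",
    "nb_nll",
    "quant_loss",
]

_FLOOR = 1e-8


def _inv_softplus(y: float) -> float:
    return float(np.log(np.expm1(y)))


@dataclass
class QuantHead:
    """Parameters of the quantitative decoder.

    s_raw and u_raw are free reals; the peak factor s_j = softplus(s_raw_j)
    and inverse-dispersion theta_j = softplus(u_raw_j) are always positive.
    Both start at softplus^-1(1) so s_j = theta_j = 1 initially (no peak
    effect, moderate over-dispersion).
    """

    w_mu: np.ndarray
    b_mu: float
    s_raw: np.ndarray
    u_raw: np.ndarray

    @classmethod
    def init(cls, dim: int, n_peaks: int, rng: np.random.Generator | None = None) -> "QuantHead":
        rng = np.random.default_rng(rng)
        one = _inv_softplus(1.0)
        return cls(
            w_mu=rng.normal(0.0, 0.1, size=dim),
            b_mu=0.0,
            s_raw=np.full(n_peaks, one),
            u_raw=np.full(n_peaks, one),
        )

    @property
    def s(self) -> np.ndarray:
        return softplus(self.s_raw)

    @property
    def theta(self) -> np.ndarray:
        return softplus(self.u_raw)

    @property
    def phi(self) -> np.ndarray:
        """Dispersion phi_j = 1 / theta_j; larger phi = stronger over-dispersion."""
        return 1.0 / self.theta


# ---------------------------------------------------------------------------
# qualitative decoder
# ---------------------------------------------------------------------------

def edge_score(zc: np.ndarray, zp: np.ndarray) -> tuple[float, float]:
    """(logit, probability) for one cell-peak pair: h = zc . zp, p = sigma(h)."""
    zc = np.asarray(zc, dtype=float)
    zp = np.asarray(zp, dtype=float)
    if zc.shape != zp.shape:
        raise ValueError("cell and peak embeddings have different dimension")
    h = float(zc @ zp)
    return h, float(expit(h))


def bpr_loss(
    triples: np.ndarray | list[tuple[int, int, int]], z: LatentSample
) -> float:
    """Mean -ln sigma(h+ - h-) over (cell, open peak, closed peak) triples.

    The mean (rather than the sum) keeps the loss scale independent of how
    many triples are sampled.
    """
    triples = np.asarray(triples, dtype=int)
    if triples.size == 0:
        raise ValueError("empty triple batch")
    cells, pos, neg = triples[:, 0], triples[:, 1], triples[:, 2]
    zc = z.z_cells[cells]
    gap = np.einsum("ij,ij->i", zc, z.z_peaks[pos] - z.z_peaks[neg])
    # -ln sigma(g) = softplus(-g), numerically stable
    return float(np.mean(np.logaddexp(0.0, -gap)))


def sample_negatives(
    cell: int, r: IncidenceMatrix, n_neg: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Uniform draws (with replacement) from the cell's closed-peak set."""
    rng = np.random.default_rng(rng)
    row = r.R.getrow(cell)
    m = r.R.shape[1]
    open_set = set(row.indices.tolist())
    if len(open_set) == m:
        raise ValueError(f"cell {cell} has no closed peaks to sample")
    closed = np.setdiff1d(np.arange(m), row.indices, assume_unique=False)
    return closed[rng.integers(0, closed.size, size=n_neg)]


def sample_negative_batch(
    cells: np.ndarray, r: IncidenceMatrix, rng: np.random.Generator
) -> np.ndarray:
    """One closed peak per listed cell, by vectorized rejection sampling.

    Repeatedly proposes uniform peaks and rejects proposals landing on an
    open entry; sparse rows make acceptance fast. Falls back to explicit
    closed-set sampling for any cell still unresolved.
    """
    cells = np.asarray(cells, dtype=int)
    m = r.R.shape[1]
    out = np.full(cells.size, -1, dtype=int)
    pending = np.arange(cells.size)
    csr = r.R.tocsr()
    for _ in range(50):
        if pending.size == 0:
            break
        prop = rng.integers(0, m, size=pending.size)
        flat = np.asarray(
            csr[cells[pending], prop]
        ).ravel()
        ok = flat == 0
        out[pending[ok]] = prop[ok]
        pending = pending[~ok]
    for idx in pending:  # dense rows: enumerate the closed set directly
        out[idx] = sample_negatives(int(cells[idx]), r, 1, rng)[0]
    return out


# ---------------------------------------------------------------------------
# quantitative decoder
# ---------------------------------------------------------------------------

def nb_mean(zc: np.ndarray, zp: np.ndarray, head: QuantHead, l_i: float, j: int = 0) -> float:
    """NB mean for one pair: mu' = l_i * s_j * softplus(w . (zc ⊙ zp) + b)."""
    if l_i <= 0:
        raise ValueError("size factor must be positive")
    mt = softplus(np.asarray(head.w_mu) @ (np.asarray(zc) * np.asarray(zp)) + head.b_mu)
    return float(l_i * head.s[j] * mt)


def nb_nll(x, mu, theta):
    """Exact NB negative log pmf under the (mu, theta) parameterization.

    -ln p = -lgamma(x+th) + lgamma(th) + lgamma(x+1)
            + (th+x) ln(mu+th) - th ln th - x ln mu.
    Vectorized; mu and theta are floored at 1e-8 to avoid log(0).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise ValueError("counts must be non-negative integers")
    mu = np.maximum(np.asarray(mu, dtype=float), _FLOOR)
    theta = np.maximum(np.asarray(theta, dtype=float), _FLOOR)
    out = (
        -gammaln(x + theta)
        + gammaln(theta)
        + gammaln(x + 1.0)
        + (theta + x) * np.log(mu + theta)
        - theta * np.log(theta)
        - x * np.log(mu)
    )
    return out if out.ndim else float(out)


def quant_mean_matrix(
    zc: np.ndarray, zp: np.ndarray, head: QuantHead, l: np.ndarray
) -> np.ndarray:
    """Dense NB mean matrix for the given cell rows vs all peaks."""
    act = (zc * head.w_mu) @ zp.T + head.b_mu
    return l[:, None] * head.s[None, :] * softplus(act)


def quant_loss(
    cells: np.ndarray,
    z: LatentSample,
    head: QuantHead,
    counts,
    l: np.ndarray,
    observed_only: bool = False,
) -> float:
    """Mean NB negative log-likelihood over the batched cells' peak vectors.

    By default every entry (zeros included) contributes — zeros are
    informative under the NB law. ``observed_only`` restricts the support to
    nonzero entries.
    """
    cells = np.asarray(cells, dtype=int)
    if cells.size == 0:
        raise ValueError("empty cell batch")
    x = np.asarray(counts[cells].todense() if hasattr(counts, "todense") else counts[cells], dtype=float)
    mu = quant_mean_matrix(z.z_cells[cells], z.z_peaks, head, np.asarray(l)[cells])
    theta = np.broadcast_to(head.theta, mu.shape)
    nll = nb_nll(x, mu, theta)
    if observed_only:
        mask = x > 0
        if not mask.any():
            raise ValueError("no observed entries in batch")
        return float(nll[mask].mean())
    return float(nll.mean())
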