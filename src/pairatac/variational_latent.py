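"""Node-wise Gaussian variational bottleneck.

Each node (cell or peak) gets a diagonal-Gaussian posterior
q(z_i) = N(mu_i, diag(sigma_i^2)). The posterior mean is the encoder readout
itself; the standard deviation is predicted from the mean by a small MLP
followed by softplus, giving node-adaptive uncertainty under heterogeneous
coverage. Sampling uses the reparameterization trick z = mu + sigma * eps,
and the posterior is pulled toward N(0, I) by a closed-form KL term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SigmaNet", "PosteriorParams", "LatentSample",
           "posterior_params", "sample", "kl_divergence", "softplus"]


def softplus(x: np.ndarray) -> np.ndarray:
    """Numerically stable ln(1 + e^x)."""
    return np.logaddexp(0.0, x)


@dataclass
class SigmaNet:
    """d -> hidden (ReLU) -> d MLP whose softplus output is sigma.

    The output bias starts negative (default -3) so initial sigma is about
    softplus(-3) ~= 0.049: small early noise stabilizes training.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    @classmethod
    def init(
        cls,
        dim: int,
        hidden: int | None = None,
        bias_init: float = -3.0,
        rng: np.random.Generator | None = None,
    ) -> "SigmaNet":
        rng = np.random.default_rng(rng)
        hidden = dim if hidden is None else hidden
        s1 = np.sqrt(2.0 / dim)
        s2 = np.sqrt(1.0 / hidden)
        return cls(
            W1=rng.normal(0.0, s1, size=(dim, hidden)),
            b1=np.zeros(hidden),
            W2=rng.normal(0.0, s2, size=(hidden, dim)),
            b2=np.full(dim, float(bias_init)),
        )

    def pre_activation(self, mu: np.ndarray) -> np.ndarray:
        """The MLP output before softplus (needed by backprop)."""
        h = np.maximum(mu @ self.W1 + self.b1, 0.0)
        return h @ self.W2 + self.b2

    def __call__(self, mu: np.ndarray) -> np.ndarray:
        return softplus(self.pre_activation(mu))


@dataclass
class PosteriorParams:
    """Posterior mean and standard deviation for all N+M nodes."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma shapes differ")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")


@dataclass
class LatentSample:
    """A reparameterized draw z = mu + sigma * eps, split into cell/peak rows."""

    z: np.ndarray
    n_cells: int

    @property
    def z_cells(self) -> np.ndarray:
        return self.z[: self.n_cells]

    @property
    def z_peaks(self) -> np.ndarray:
        return self.z[self.n_cells:]


def posterior_params(ebar: np.ndarray, net: SigmaNet) -> PosteriorParams:
    """mu = Ē; sigma = softplus(MLP(mu)) > 0 elementwise."""
    ebar = np.asarray(ebar, dtype=float)
    if not np.all(np.isfinite(ebar)):
        raise ValueError("non-finite encoder output")
    return PosteriorParams(mu=ebar, sigma=net(ebar))


def sample(
    p: PosteriorParams,
    n_cells: int,
    rng_seed: int | np.random.Generator | None = None,
    deterministic: bool = False,
) -> LatentSample:
    """Draw z = mu + sigma * eps; ``deterministic`` forces eps = 0 (z = mu)."""
    if deterministic:
        return LatentSample(z=p.mu.copy(), n_cells=n_cells)
    rng = np.random.default_rng(rng_seed)
    eps = rng.standard_normal(p.mu.shape)
    return LatentSample(z=p.mu + p.sigma * eps, n_cells=n_cells)


def kl_divergence(p: PosteriorParams) -> float:
    """KL(q || N(0, I)) summed over all nodes and latent dimensions.

    Closed form per coordinate: (sigma^2 + mu^2 - 1 - ln sigma^2) / 2.
    Zero exactly when mu = 0 and sigma = 1.
    """
    s2 = p.sigma**2
    return float(0.5 * np.sum(s2 + p.mu**2 - 1.0 - np.log(s2)))
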