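"""Log-normal and log-normal-mixture distribution objects.

All log-scale parameters are natural-log ppb throughout the package;
every public quantile/CDF back-transforms to ppb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LognormalFit",
    "LognormalMixtureDistribution",
    "lognormal_from_quantiles",
    "lognormal_from_quantile",
]


@dataclass(frozen=True)
class LognormalFit:
    """A log-normal distribution on the ppb scale: ln X ~ N(mu, sigma^2).

    Attributes
    ----------
    mu, sigma : float
        Mean and standard deviation of ln(concentration/ppb); sigma >= 0
        (sigma == 0 marks a degenerate, point-mass fit).
    n : int
        Number of observations behind the fit (0 when constructed from
        quantile anchors rather than data).
    method : str
        How the parameters were obtained: ``"mle_complete"``,
        ``"ros_regression"``, ``"em"``, or ``"quantile_anchor"``.
    """

    mu: float
    sigma: float
    n: int = 0
    method: str = "quantile_anchor"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def quantile(self, p) -> np.ndarray | float:
        """exp(mu + z(p) * sigma), the p-th quantile in ppb."""
        p = np.asarray(p, dtype=float)
        out = np.exp(self.mu + stats.norm.ppf(p) * self.sigma)
        return float(out) if out.ndim == 0 else out

    def cdf(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if self.sigma == 0:
            out = (x >= np.exp(self.mu)).astype(float)
        else:
            out = stats.norm.cdf((np.log(x) - self.mu) / self.sigma)
        return float(out) if out.ndim == 0 else out

    def rvs(self, size, rng: np.random.Generator) -> np.ndarray:
        return np.exp(self.mu + self.sigma * rng.standard_normal(size))


def lognormal_from_quantiles(
    p1: float, q1: float, p2: float, q2: float
) -> LognormalFit:
    """Calibrate a log-normal from two quantile anchors.

    Solves for (mu, sigma) such that the log-normal CDF equals ``p1`` at
    ``q1`` ppb and ``p2`` at ``q2`` ppb:

        sigma = (ln q2 - ln q1) / (z(p2) - z(p1))
        mu    = ln q1 - z(p1) * sigma

    where z is the standard normal quantile function.

    Raises
    ------
    ValueError
        If probabilities or quantiles are not strictly ordered or lie
        outside their valid ranges.
    """
    if not (0 < p1 < p2 < 1):
        raise ValueError("need 0 < p1 < p2 < 1")
    if not (0 < q1 < q2):
        raise ValueError("need 0 < q1 < q2")
    z1, z2 = stats.norm.ppf([p1, p2])
    sigma = (np.log(q2) - np.log(q1)) / (z2 - z1)
    mu = np.log(q1) - z1 * sigma
    return LognormalFit(mu=float(mu), sigma=float(sigma))


def lognormal_from_quantile(p: float, q: float, sigma: float) -> LognormalFit:
    """Calibrate a log-normal from a single quantile anchor and a stated
    sigma: mu = ln q - z(p) * sigma."""
    if not (0 < p < 1):
        raise ValueError("need 0 < p < 1")
    if q <= 0:
        raise ValueError("need q > 0")
    if sigma <= 0:
        raise ValueError("need sigma > 0")
    mu = np.log(q) - stats.norm.ppf(p) * sigma
    return LognormalFit(mu=float(mu), sigma=float(sigma))


class LognormalMixtureDistribution:
    """Finite mixture of log-normal components, ordered low to high mu.

    The overall CDF is the weight-sum of component CDFs:
    F(x) = sum_j w_j * Phi((ln x - mu_j) / sigma_j).
    """

    def __init__(self, weights: Sequence[float], components: Sequence[LognormalFit]):
        weights = np.asarray(weights, dtype=float)
        if len(weights) != len(components):
            raise ValueError("weights and components must have equal length")
        if len(weights) == 0:
            raise ValueError("need at least one component")
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-10:
            raise ValueError("weights must be non-negative and sum to 1")
        order = np.argsort([c.mu for c in components], kind="stable")
        self.weights = weights[order]
        self.components = [components[i] for i in order]

    @property
    def k(self) -> int:
        return len(self.components)

    def __repr__(self) -> str:
        parts = ", ".join(
            f"{w:.3f}*LN({c.mu:.3f},{c.sigma:.3f})"
            for w, c in zip(self.weights, self.components)
        )
        return f"<LognormalMixtureDistribution {parts}>"

    def cdf(self, x) -> np.ndarray | float:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros_like(x)
        for w, c in zip(self.weights, self.components):
            out += w * np.asarray(c.cdf(x))
        return float(out[0]) if out.size == 1 else out

    def component_quantile(self, j: int, p: float) -> float:
        """Quantile of component ``j`` (1-based index, low to high)."""
        if not 1 <= j <= self.k:
            raise IndexError(f"component index {j} out of range 1..{self.k}")
        if not 0 < p < 1:
            raise ValueError("need 0 < p < 1")
        return float(self.components[j - 1].quantile(p))

    def quantile(self, p: float, rtol: float = 1e-10) -> float:
        """Numeric inversion of the mixture CDF by bracketed bisection.

        The bracket is expanded geometrically until F brackets p, then
        refined to relative tolerance ``rtol``.
        """
        if not 0 < p < 1:
            raise ValueError("need 0 < p < 1")
        if self.k == 1:
            return self.component_quantile(1, p)
        # start from the envelope of component quantiles
        lo = min(c.quantile(p) for c in self.components)
        hi = max(c.quantile(p) for c in self.components)
        while self.cdf(lo) > p:
            lo /= 2.0
        while self.cdf(hi) < p:
            hi *= 2.0
        while hi - lo > rtol * hi:
            mid = 0.5 * (lo + hi)
            if self.cdf(mid) < p:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def rvs(self, size, rng: np.random.Generator) -> np.ndarray:
        """Draw concentrations (ppb): component membership from the
        weights, then a log-normal draw from the member component."""
        size = tuple(np.atleast_1d(size))
        comp = rng.choice(self.k, size=size, p=self.weights)
        mus = np.array([c.mu for c in self.components])
        sigmas = np.array([c.sigma for c in self.components])
        z = rng.standard_normal(size)
        return np.exp(mus[comp] + sigmas[comp] * z)

    def plot_cdf(self, ax=None, x=None, **kw):
        """Plot the mixture CDF on a log concentration axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if x is None:
            x = np.geomspace(self.quantile(0.001), self.quantile(0.999), 400)
        ax.plot(x, self.cdf(x), **kw)
        ax.set_xscale("log")
        ax.set_xlabel("lead concentration (ppb)")
        ax.set_ylabel("cumulative probability")
        return ax
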