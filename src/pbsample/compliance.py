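"""Regulatory compliance statistics and Monte Carlo exceedance analysis.

Under the Lead and Copper Rule a water system is out of compliance when
the "count-up" 90th percentile of a compliance round's tap samples
exceeds the 15 ppb action level: sort the round ascending and take the
value at rank 0.9 n. The Monte Carlo analysis here asks what that
statistic would look like if a compliance round of ~150 homes were
drawn at random from a community-wide concentration distribution
(a fitted mixture) instead of from targeted Tier I sites: draw 150
values, compute the count-up p90, repeat 10,000 times, and read off the
probability that a random round would register an exceedance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import LognormalMixtureDistribution

__all__ = [
    "ComplianceConfig",
    "MonteCarloConfig",
    "ExceedanceCurve",
    "countup_p90",
    "simulate_p90_distribution",
    "exceedance_probability",
    "compliance_status",
]


@dataclass(frozen=True)
class ComplianceConfig:
    """Action level (ppb) and the regulatory percentile (fixed at 0.9)."""

    action_level: float = 15.0
    percentile: float = 0.9

    def __post_init__(self) -> None:
        if self.action_level <= 0:
            raise ValueError("action_level must be positive")


@dataclass(frozen=True)
class MonteCarloConfig:
    """Monte Carlo design: draws per simulated compliance round
    (default 150, the typical reported round size) and number of
    replicates (default 10000)."""

    n_draw: int = 150
    n_rep: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draw < 5:
            raise ValueError("n_draw must be >= 5")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")


def _countup_from_sorted(sorted_vals: np.ndarray, mode: str) -> np.ndarray:
    """Count-up percentile on pre-sorted rows (2-D: one round per row)."""
    n = sorted_vals.shape[-1]
    r = 0.9 * n
    if abs(r - round(r)) < 1e-9:  # integer rank: the r-th ascending value
        return sorted_vals[..., int(round(r)) - 1]
    if mode == "round_up":
        return sorted_vals[..., int(np.ceil(r)) - 1]
    lo = int(np.floor(r))
    frac = r - lo
    return (1 - frac) * sorted_vals[..., lo - 1] + frac * sorted_vals[..., lo]


def countup_p90(values, censored=None, reporting_limits=None, mode: str = "interpolate") -> float:
    """The LCR count-up 90th percentile.

    Sort ascending (censored values enter at their reporting limit — the
    upper-bound convention, independent of any imputation) and take the
    value at rank r = 0.9 n. For integer r this is the r-th ascending
    value; for non-integer r the default interpolates linearly between
    the bracketing order statistics, and ``mode="round_up"`` instead
    takes the ceil(r)-th value (a strict reading kept for sensitivity
    checks).

    Raises
    ------
    ValueError
        n < 5 (the regulatory method is undefined for very small
        rounds) or unknown mode.
    """
    if mode not in ("interpolate", "round_up"):
        raise ValueError("mode must be 'interpolate' or 'round_up'")
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be 1-D")
    if values.size < 5:
        raise ValueError("count-up p90 needs n >= 5")
    if censored is not None:
        censored = np.asarray(censored, dtype=bool)
        if reporting_limits is None:
            raise ValueError("reporting_limits required with censored flags")
        values = np.where(censored, np.asarray(reporting_limits, dtype=float), values)
    return float(_countup_from_sorted(np.sort(values), mode))


@dataclass(frozen=True)
class ExceedanceCurve:
    """Empirical distribution of simulated count-up 90th percentiles.

    ``simulated_p90s`` is sorted ascending with length ``config.n_rep``.
    """

    simulated_p90s: np.ndarray
    config: MonteCarloConfig
    source_model: LognormalMixtureDistribution

    def exceedance_probability(self, threshold: float) -> float:
        return exceedance_probability(self, threshold)

    def to_frame(self):
        """Two-column table (p90_ppb, exceedance_probability)."""
        import pandas as pd

        n = len(self.simulated_p90s)
        return pd.DataFrame(
            {
                "p90_ppb": self.simulated_p90s,
                # P(simulated p90 > x) evaluated at each order statistic
                "exceedance_probability": 1.0 - np.arange(1, n + 1) / n,
            }
        )

    def plot(self, ax=None, action_level: float = 15.0, **kw):
        """Probability-of-exceedance plot of the simulated p90s."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.to_frame()
        ax.plot(df["p90_ppb"], df["exceedance_probability"], **kw)
        ax.axvline(action_level, color="red", lw=1)
        ax.set_xlabel("count-up 90th percentile (ppb)")
        ax.set_ylabel("probability of exceedance")
        return ax


def simulate_p90_distribution(
    model: LognormalMixtureDistribution,
    mc: MonteCarloConfig = MonteCarloConfig(),
    mode: str = "interpolate",
) -> ExceedanceCurve:
    """Simulate the count-up p90 of repeated random compliance rounds.

    Each replicate draws ``n_draw`` concentrations from the mixture and
    computes the count-up 90th percentile; replicates are collected
    into an :class:`ExceedanceCurve`. Deterministic given ``mc.seed``.
    """
    if hasattr(model, "mixture"):  # accept fitted results transparently
        model = model.mixture
    rng = np.random.default_rng(mc.seed)
    draws = model.rvs((mc.n_rep, mc.n_draw), rng)
    draws.sort(axis=1)
    p90s = np.sort(_countup_from_sorted(draws, mode))
    return ExceedanceCurve(simulated_p90s=p90s, config=mc, source_model=model)


def exceedance_probability(curve: ExceedanceCurve, threshold: float) -> float:
    """Fraction of simulated p90s strictly greater than ``threshold``."""
    p90s = curve.simulated_p90s
    if len(p90s) == 0:
        raise ValueError("empty exceedance curve")
    return float(np.mean(p90s > threshold))


def compliance_status(p90: float, config: ComplianceConfig = ComplianceConfig()) -> bool:
    """True when the round's p90 strictly exceeds the action level
    (15.0 ppb exactly does not trigger an exceedance)."""
    if p90 < 0:
        raise ValueError("p90 must be non-negative")
    return p90 > config.action_level
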