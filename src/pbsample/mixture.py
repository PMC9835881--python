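"""k-component log-normal mixture fitting by EM, with BIC selection.

Community-wide tap sampling mixes two very different kinds of homes:
a majority with little or no lead plumbing (low concentrations, heavily
censored) and a minority resembling regulatory Tier I sites (lead
service lines or solder, long right tail). A single log-normal fits
such data poorly; a two-component mixture separates the groups and lets
each be summarised by its own quantiles.

Fitting runs on the natural-log scale as a standard Gaussian-mixture
EM, after censored records have been completed by ROS imputation
(see :mod:`pbsample.censored`). Model order is chosen by BIC,

    BIC = -2 loglik + (3k - 1) ln n,

with 3k - 1 free parameters (k means, k standard deviations, k - 1
independent weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .distributions import LognormalFit, LognormalMixtureDistribution
from .censored import NotEstimableError

__all__ = [
    "DegenerateFitError",
    "fit_mixture_em",
    "select_k",
    "component_quantile",
    "mixture_quantile",
    "LognormalMixture",
    "LognormalMixtureResults",
    "save_mixture",
    "load_mixture",
]

_LOG_2PI = np.log(2.0 * np.pi)


class DegenerateFitError(RuntimeError):
    """All EM restarts collapsed onto a degenerate component."""


# ----------------------------------------------------------------------
# initialisation
# ----------------------------------------------------------------------
def _quantile_split_init(logs: np.ndarray, k: int):
    """Seed components by splitting the sorted log data at upper
    quantiles (at the 90th percentile for k=2), reflecting the
    long-right-tail structure of tap-lead data."""
    splits = {1: [], 2: [0.90], 3: [0.80, 0.95]}[k]
    edges = np.quantile(logs, [0.0, *splits, 1.0])
    edges[-1] = np.inf
    mu, sigma, w = np.empty(k), np.empty(k), np.empty(k)
    overall_sd = max(logs.std(), 1e-3)
    for j in range(k):
        seg = logs[(logs >= edges[j]) & (logs < edges[j + 1])]
        if seg.size < 2:
            seg = logs
        mu[j] = seg.mean()
        sigma[j] = max(seg.std(), 0.1 * overall_sd)
        w[j] = max(seg.size, 1)
    return mu, sigma, w / w.sum()


def _random_init(logs: np.ndarray, k: int, rng: np.random.Generator):
    mu = rng.choice(logs, size=k, replace=False)
    sigma = np.full(k, max(logs.std(), 1e-3))
    w = np.full(k, 1.0 / k)
    return mu, sigma, w


# ----------------------------------------------------------------------
# EM core
# ----------------------------------------------------------------------
def _em_once(logs, mu, sigma, w, tol, max_iter, var_floor):
    """One EM run. Returns (mu, sigma, w, loglik, n_iter, converged,
    trace) or None when a component collapses; trace is the per-iteration
    log-likelihood sequence (non-decreasing by the EM guarantee)."""
    x = logs[:, None]
    n = logs.size
    ll_old = -np.inf
    converged = False
    it = 0
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        log_dens = (
            np.log(w)
            - np.log(sigma)
            - 0.5 * _LOG_2PI
            - 0.5 * ((x - mu) / sigma) ** 2
        )
        norm = logsumexp(log_dens, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        resp = np.exp(log_dens - norm[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 2.0):
            return None  # component starved of observations
        w = nk / n
        mu = (resp * x).sum(axis=0) / nk
        var = (resp * (x - mu) ** 2).sum(axis=0) / nk
        if np.any(var < var_floor):
            return None  # variance collapse
        sigma = np.sqrt(var)
        if ll - ll_old <= tol * abs(ll_old) and np.isfinite(ll_old):
            converged = True
            break
        ll_old = ll
    return mu, sigma, w, ll, it, converged, trace


def fit_mixture_em(
    log_values,
    k: int,
    init: str = "quantile_split",
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    var_floor: float = 1e-6,
    max_retries: int = 5,
) -> "LognormalMixtureResults":
    """Fit a k-component Gaussian mixture to log-scale values by EM.

    Parameters
    ----------
    log_values : array-like
        ln(concentration/ppb) values; must have n >= 10 k.
    k : int in {1, 2, 3}
    init : {"quantile_split", "random"}
        Initialisation; quantile_split seeds the upper component(s) from
        the right tail, random draws component means from the data.
    seed : int, optional
        Seeds the random initialisation and collapse restarts.
    tol : float
        Stop when the relative log-likelihood improvement drops below
        this (the likelihood never decreases between EM iterations).
    var_floor : float
        Minimum component variance on the log scale; hitting it marks
        the run degenerate and triggers a seeded restart (up to
        ``max_retries``), after which :class:`DegenerateFitError` is
        raised.

    Returns
    -------
    LognormalMixtureResults with components relabelled ascending in mu.
    Non-convergence within ``max_iter`` is reported via
    ``converged=False``, not an exception.
    """
    logs = np.sort(np.asarray(log_values, dtype=float))
    n = logs.size
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    if n < 10 * k:
        raise NotEstimableError(f"need n >= {10 * k} for k={k}")
    if init not in ("quantile_split", "random"):
        raise ValueError("init must be 'quantile_split' or 'random'")

    if k == 1:
        # EM fixed point: the closed-form Gaussian MLE (n denominator)
        mu = float(logs.mean())
        sigma = float(max(logs.std(), np.sqrt(var_floor)))
        ll = float(
            -0.5 * n * _LOG_2PI - n * np.log(sigma)
            - 0.5 * np.sum(((logs - mu) / sigma) ** 2)
        )
        res = LognormalMixtureResults(
            weights=np.array([1.0]),
            components=[LognormalFit(mu, sigma, n=n, method="em")],
            loglik=ll, n=n, converged=True, n_iter=0, seed=seed,
        )
        res.loglik_trace = [ll]
        return res

    rng = np.random.default_rng(seed)
    attempt_init = init
    for _ in range(max_retries + 1):
        if attempt_init == "quantile_split":
            mu0, s0, w0 = _quantile_split_init(logs, k)
        else:
            mu0, s0, w0 = _random_init(logs, k, rng)
        out = _em_once(logs, mu0, s0, w0, tol, max_iter, var_floor)
        if out is not None:
            mu, sigma, w, ll, it, conv, trace = out
            order = np.argsort(mu, kind="stable")
            comps = [
                LognormalFit(float(mu[j]), float(sigma[j]), n=n, method="em")
                for j in order
            ]
            res = LognormalMixtureResults(
                weights=w[order], components=comps, loglik=ll,
                n=n, converged=conv, n_iter=it, seed=seed,
            )
            res.loglik_trace = trace
            return res
        attempt_init = "random"  # collapse: retry from a fresh random start
    raise DegenerateFitError(
        f"EM collapsed on every restart (k={k}, n={n}); "
        "the data may not support this many components"
    )


def select_k(
    log_values,
    candidate_ks: Sequence[int] = (1, 2, 3),
    seed: int | None = None,
    n_restarts: int = 10,
    **em_kw,
) -> "LognormalMixtureResults":
    """Fit each candidate k with multiple restarts and return the
    minimum-BIC model; the full BIC table is attached as ``bic_table``.

    The first restart uses the quantile-split initialisation, the rest
    random starts with seeds spawned from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    best_per_k: dict[int, LognormalMixtureResults] = {}
    for k in candidate_ks:
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_restarts)]
        best = None
        for r in range(max(n_restarts, 1)):
            init = "quantile_split" if r == 0 else "random"
            try:
                res = fit_mixture_em(
                    log_values, k, init=init, seed=child_seeds[r % len(child_seeds)],
                    **em_kw,
                )
            except (DegenerateFitError, NotEstimableError):
                continue
            if best is None or res.loglik > best.loglik:
                best = res
        if best is not None:
            best_per_k[k] = best
    if not best_per_k:
        raise NotEstimableError("no candidate k produced a non-degenerate fit")
    table = pd.DataFrame(
        {
            "k": list(best_per_k),
            "loglik": [r.loglik for r in best_per_k.values()],
            "bic": [r.bic for r in best_per_k.values()],
            "converged": [r.converged for r in best_per_k.values()],
        }
    ).sort_values("k", ignore_index=True)
    winner = min(best_per_k.values(), key=lambda r: r.bic)
    winner.bic_table = table
    return winner


# ----------------------------------------------------------------------
# quantiles (thin wrappers over the distribution object)
# ----------------------------------------------------------------------
def _as_distribution(model) -> LognormalMixtureDistribution:
    if isinstance(model, LognormalMixtureDistribution):
        return model
    return model.mixture


def component_quantile(model, j: int, p: float) -> float:
    """p-th quantile (ppb) of component j (1-based, low to high)."""
    return _as_distribution(model).component_quantile(j, p)


def mixture_quantile(model, p: float) -> float:
    """p-th quantile (ppb) of the overall mixture, by numeric inversion
    of the weight-summed CDF."""
    return _as_distribution(model).quantile(p)


# ----------------------------------------------------------------------
# model / results interface
# ----------------------------------------------------------------------
class LognormalMixture:
    """Log-normal mixture model for complete (imputed) concentrations.

    Parameters
    ----------
    values : array-like
        Positive concentrations in ppb (typically a ROS-completed
        dataset's values).
    k : int or sequence of int
        Number of components, or candidates for BIC selection.

    Examples
    --------
    >>> res = LognormalMixture(values, k=2).fit(seed=0)
    >>> res.weights, [c.mu for c in res.components]
    >>> res.component_quantile(2, 0.9)   # p90 of the high component
    >>> print(res.summary())
    """

    def __init__(self, values, k: int | Sequence[int] = 2):
        values = np.asarray(values, dtype=float)
        if np.any(values <= 0):
            raise ValueError("all concentrations must be positive")
        self.values = values
        self.log_values = np.log(values)
        self.k = k

    @classmethod
    def from_dataframe(cls, df, column: str = "reported_value", k=2):
        return cls(df[column].to_numpy(dtype=float), k=k)

    def fit(self, seed: int | None = None, **kw) -> "LognormalMixtureResults":
        """Fit by EM; when ``k`` is a sequence, fit every candidate and
        return the minimum-BIC model (with its BIC table)."""
        if np.iterable(self.k):
            res = select_k(self.log_values, candidate_ks=tuple(self.k), seed=seed, **kw)
        else:
            res = fit_mixture_em(self.log_values, int(self.k), seed=seed, **kw)
        res.model = self
        return res


class LognormalMixtureResults:
    """Fitted mixture: weights and components (ascending mu), the
    log-likelihood, BIC, and convergence diagnostics."""

    def __init__(self, weights, components, loglik, n, converged, n_iter, seed):
        self.weights = np.asarray(weights, dtype=float)
        self.components: list[LognormalFit] = list(components)
        self.loglik = float(loglik)
        self.n = int(n)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.seed = seed
        self.bic_table: pd.DataFrame | None = None
        self.model: LognormalMixture | None = None
        self.loglik_trace: list[float] = []

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def n_params(self) -> int:
        return 3 * self.k - 1

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n)

    @property
    def llf(self) -> float:  # statsmodels-style alias
        return self.loglik

    @property
    def mixture(self) -> LognormalMixtureDistribution:
        return LognormalMixtureDistribution(self.weights, self.components)

    def component_quantile(self, j: int, p: float) -> float:
        return component_quantile(self, j, p)

    def quantile(self, p: float) -> float:
        return mixture_quantile(self, p)

    def simulate_compliance(self, mc_config=None):
        """Monte Carlo distribution of the regulatory count-up 90th
        percentile under repeated compliance rounds drawn from this
        fitted mixture; see :func:`pbsample.compliance.simulate_p90_distribution`."""
        from .compliance import MonteCarloConfig, simulate_p90_distribution

        return simulate_p90_distribution(self.mixture, mc_config or MonteCarloConfig())

    def summary(self) -> str:
        lines = [
            f"Log-normal mixture (k={self.k}), EM on the log scale",
            "=" * 56,
            f"n = {self.n}   loglik = {self.loglik:.3f}   BIC = {self.bic:.3f}",
            f"converged = {self.converged} in {self.n_iter} iterations",
            f"{'comp':<6}{'weight':>9}{'mu':>10}{'sigma':>9}{'median':>10}{'p90':>10}",
        ]
        for j, (w, c) in enumerate(zip(self.weights, self.components), start=1):
            lines.append(
                f"{j:<6}{w:>9.4f}{c.mu:>10.4f}{c.sigma:>9.4f}"
                f"{c.quantile(0.5):>10.3f}{c.quantile(0.9):>10.3f}"
            )
        if self.bic_table is not None:
            lines.append("BIC table:")
            lines.append(self.bic_table.to_string(index=False))
        return "\n".join(lines)

    def plot_cdf(self, ax=None, **kw):
        return self.mixture.plot_cdf(ax=ax, **kw)


# ----------------------------------------------------------------------
# flat key-value serialisation
# ----------------------------------------------------------------------
def save_mixture(res: LognormalMixtureResults, path) -> None:
    """Write a fitted mixture as flat ``key = value`` text."""
    lines = [f"k = {res.k}", f"n = {res.n}", f"loglik = {float(res.loglik)!r}",
             f"bic = {float(res.bic)!r}", f"converged = {res.converged}",
             f"seed = {res.seed}"]
    for j, (w, c) in enumerate(zip(res.weights, res.components), start=1):
        lines += [
            f"weight_{j} = {float(w)!r}",
            f"mu_{j} = {float(c.mu)!r}",
            f"sigma_{j} = {float(c.sigma)!r}",
        ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_mixture(path) -> LognormalMixtureResults:
    kv = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            key, val = line.split("=", 1)
            kv[key.strip()] = val.strip()
    k = int(kv["k"])
    comps = [
        LognormalFit(float(kv[f"mu_{j}"]), float(kv[f"sigma_{j}"]),
                     n=int(kv["n"]), method="em")
        for j in range(1, k + 1)
    ]
    weights = np.array([float(kv[f"weight_{j}"]) for j in range(1, k + 1)])
    return LognormalMixtureResults(
        weights=weights, components=comps, loglik=float(kv["loglik"]),
        n=int(kv["n"]), converged=kv["converged"] == "True",
        n_iter=0, seed=None if kv.get("seed") in (None, "None") else int(kv["seed"]),
    )
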