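"""Left-censored statistics: multi-limit regression on order statistics.

Laboratories report lead below their reporting limit (RL) as a
nondetect, so a sampling-program dataset is left-censored — often at
several limits at once because different laboratories (RLs 1-4 ppb)
analysed different samples. The semiparametric ("robust") regression on
order statistics, or ROS, treatment used here:

1. computes censoring-aware plotting positions for every record with
   the multiply-censored threshold recursion (Helsel-Cohn),
2. regresses the log of the *detected* values on the normal quantiles of
   their plotting positions,
3. imputes each censored record from the fitted line at its own
   position, while never altering an observed detect.

The result is a complete, continuous dataset on which ordinary
log-normal and mixture fitting can proceed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .distributions import LognormalFit
from .records import CensoredDataset, SampleRecord

__all__ = [
    "NotEstimableError",
    "DegenerateFitWarning",
    "SummaryStats",
    "KsGofResult",
    "helsel_cohn_positions",
    "ros_impute",
    "fit_lognormal_mle",
    "summary_stats",
    "ks_gof",
    "CensoredLognormal",
    "CensoredLognormalResults",
]


class NotEstimableError(ValueError):
    """Raised when a quantity cannot be estimated from the data given
    (e.g. ROS on an all-censored dataset)."""


class DegenerateFitWarning(UserWarning):
    """Emitted when a fit collapses (e.g. sigma == 0 on constant data)."""


# ----------------------------------------------------------------------
# plotting positions
# ----------------------------------------------------------------------
def helsel_cohn_positions(dataset: CensoredDataset) -> np.ndarray:
    """Censoring-aware plotting positions, one per record in input order.

    Uses the multiply-censored construction: sort the distinct censoring
    thresholds ascending, then compute the probability of exceeding each
    threshold by the descending recursion

        pe_j = pe_{j+1} + A_j / (A_j + B_j) * (1 - pe_{j+1})

    where A_j counts detects in [L_j, L_{j+1}) and B_j counts all
    observations known to lie below L_j (detects below it plus
    nondetects censored at or below it). Detects in an interval receive
    Weibull-type positions interpolated between the bracketing
    non-exceedance probabilities; nondetects at a limit are spread
    uniformly below that limit's non-exceedance probability.

    With no censored records the recursion collapses to the single-limit
    Weibull positions r/(n+1).

    Returns
    -------
    ndarray of float in (0, 1), aligned with ``dataset.records``.

    Raises
    ------
    NotEstimableError
        If the dataset contains no uncensored record.
    """
    n = len(dataset)
    if n == 0:
        raise NotEstimableError("empty dataset")
    values = dataset.values
    cens = dataset.censored_mask
    limits = dataset.limits
    if not np.any(~cens):
        raise NotEstimableError("all records censored; ROS needs >=1 detect")

    thresholds = np.unique(limits[cens])  # ascending censoring limits
    m = len(thresholds)
    # interval edges: L_0 = 0 below the lowest limit, L_{m+1} = inf
    edges = np.concatenate([[0.0], thresholds, [np.inf]])

    det_vals = values[~cens]
    A = np.empty(m + 1)  # detects in [L_j, L_{j+1}), j = 0..m
    for j in range(m + 1):
        A[j] = np.sum((det_vals >= edges[j]) & (det_vals < edges[j + 1]))
    B = np.empty(m + 1)  # observations known to be below L_j
    B[0] = 0.0
    for j in range(1, m + 1):
        B[j] = np.sum(det_vals < edges[j]) + np.sum(cens & (limits <= edges[j]))

    pe = np.zeros(m + 2)  # pe[j] = P(X > L_j); pe[m+1] = 0
    for j in range(m, -1, -1):
        denom = A[j] + B[j]
        frac = A[j] / denom if denom > 0 else 0.0
        pe[j] = pe[j + 1] + frac * (1.0 - pe[j + 1])
    pe[0] = 1.0  # every concentration exceeds zero

    positions = np.empty(n)
    # detects: rank within their interval by value, ties by input order
    det_idx = np.flatnonzero(~cens)
    for j in range(m + 1):
        in_int = det_idx[(values[det_idx] >= edges[j]) & (values[det_idx] < edges[j + 1])]
        if len(in_int) == 0:
            continue
        order = in_int[np.argsort(values[in_int], kind="stable")]
        r = np.arange(1, len(order) + 1)
        positions[order] = (1.0 - pe[j]) + (pe[j] - pe[j + 1]) * r / (len(order) + 1)
    # nondetects: spread uniformly below their own limit's
    # non-exceedance probability, in input order
    for j in range(1, m + 1):
        at_limit = np.flatnonzero(cens & (limits == thresholds[j - 1]))
        r = np.arange(1, len(at_limit) + 1)
        positions[at_limit] = (1.0 - pe[j]) * r / (len(at_limit) + 1)
    return positions


# ----------------------------------------------------------------------
# imputation
# ----------------------------------------------------------------------
def ros_impute(dataset: CensoredDataset, clamp_factor: float = 0.999) -> CensoredDataset:
    """Impute censored records from the ROS regression line.

    Fits ordinary least squares of ln(detect value) on the normal
    quantiles of the detect plotting positions, then evaluates the line
    at each censored record's position. Observed detects are never
    altered (the semiparametric, "robust" variant). An imputed value that
    the fitted line would place above the record's own reporting limit is
    clamped to ``clamp_factor * RL`` with a warning, preserving the
    below-limit semantics.

    Datasets with no censored records are returned unchanged.

    Raises
    ------
    NotEstimableError
        Fewer than 2 distinct detected values (no regression slope).
    ValueError
        Non-positive detected value.
    """
    if dataset.n_censored == 0:
        return dataset
    detects = dataset.detects
    if np.any(detects <= 0):
        raise ValueError("detected concentrations must be positive")
    if len(np.unique(detects)) < 2:
        raise NotEstimableError("ROS regression needs >=2 distinct detects")

    positions = helsel_cohn_positions(dataset)
    cens = dataset.censored_mask
    z_det = stats.norm.ppf(positions[~cens])
    y_det = np.log(dataset.values[~cens])
    slope, intercept = np.polyfit(z_det, y_det, 1)

    imputed_vals = np.exp(intercept + slope * stats.norm.ppf(positions[cens]))
    limits = dataset.limits[cens]
    over = imputed_vals >= limits
    if np.any(over):
        warnings.warn(
            f"{int(over.sum())} imputed value(s) exceeded their reporting "
            f"limit and were clamped to {clamp_factor} * RL",
            UserWarning,
            stacklevel=2,
        )
        imputed_vals = np.where(over, clamp_factor * limits, imputed_vals)

    new_records: list[SampleRecord] = []
    it = iter(imputed_vals)
    for rec in dataset.records:
        if rec.censored:
            new_records.append(
                replace(rec, reported_value=float(next(it)), imputed=True)
            )
        else:
            new_records.append(rec)
    return dataset.with_records(new_records)


# ----------------------------------------------------------------------
# complete-data fitting and summaries
# ----------------------------------------------------------------------
def fit_lognormal_mle(values) -> LognormalFit:
    """Fit a log-normal to complete (uncensored or imputed) data.

    mu is the mean of ln(values); sigma the standard deviation with the
    n-1 denominator (so two-point examples are exact).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise NotEstimableError("need n >= 2")
    if np.any(values <= 0):
        raise ValueError("all values must be positive")
    logs = np.log(values)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=1))
    if sigma == 0:
        warnings.warn("constant data: sigma = 0", DegenerateFitWarning, stacklevel=2)
    return LognormalFit(mu=mu, sigma=sigma, n=values.size, method="mle_complete")


@dataclass(frozen=True)
class SummaryStats:
    """Censoring-aware summary of one dataset.

    ``median`` is None when the middle order statistic is itself
    censored ("below RL" in report output). ``p90_empirical`` uses the
    regulatory count-up convention with censored values entered at their
    reporting limit; None when n < 5 (the convention is undefined there).
    """

    n: int
    n_bdl: int
    frac_bdl: float
    median: float | None
    median_below_rl: bool
    p90_empirical: float | None


def summary_stats(dataset: CensoredDataset) -> SummaryStats:
    from .compliance import countup_p90  # local import avoids a cycle

    n = len(dataset)
    if n == 0:
        raise ValueError("empty dataset")
    cens = dataset.censored_mask
    values = dataset.values  # censored at RL
    n_bdl = int(cens.sum())

    order = np.argsort(values, kind="stable")
    mid = [(n - 1) // 2] if n % 2 else [n // 2 - 1, n // 2]
    mid_censored = any(bool(cens[order[i]]) for i in mid)
    median = None if mid_censored else float(np.median(values))

    p90 = countup_p90(values) if n >= 5 else None
    return SummaryStats(
        n=n,
        n_bdl=n_bdl,
        frac_bdl=n_bdl / n,
        median=median,
        median_below_rl=mid_censored,
        p90_empirical=p90,
    )


# ----------------------------------------------------------------------
# goodness of fit
# ----------------------------------------------------------------------
_GOF_CAVEAT = (
    "Samples from one program share temporal/spatial structure, so the "
    "independence assumption behind this p-value is approximate; treat "
    "it as a broad-scale indication rather than a precise probability."
)


@dataclass(frozen=True)
class KsGofResult:
    statistic: float
    pvalue: float
    n_boot: int
    warning: str = _GOF_CAVEAT


def _ks_statistic_normal(logs: np.ndarray, mu, sigma) -> np.ndarray:
    """Rowwise one-sample KS statistic of ``logs`` against N(mu, sigma).

    ``logs`` may be 1-D (one sample) or 2-D (one sample per row, with
    mu/sigma arrays of matching length).
    """
    logs = np.atleast_2d(np.sort(logs, axis=-1))
    mu = np.atleast_1d(mu)[:, None]
    sigma = np.atleast_1d(sigma)[:, None]
    n = logs.shape[1]
    u = stats.norm.cdf((logs - mu) / sigma)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u, axis=1)
    d_minus = np.max(u - (i - 1) / n, axis=1)
    return np.maximum(d_plus, d_minus)


def ks_gof(
    values,
    fit: LognormalFit,
    n_boot: int = 500,
    seed: int | None = None,
) -> KsGofResult:
    """One-sample KS test of log values against the fitted normal, with a
    parametric-bootstrap p-value.

    Because (mu, sigma) were estimated from the same data, the classical
    KS null distribution is invalid; each bootstrap replicate draws n
    values from the fitted distribution, *refits* mu and sigma, and
    recomputes the statistic. The p-value is the (add-one) fraction of
    replicates at least as extreme as observed.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need n >= 5")
    if fit.sigma == 0:
        raise NotEstimableError("sigma = 0: KS test not estimable")
    if n_boot < 100:
        warnings.warn(
            "n_boot < 100 gives a coarse bootstrap p-value", UserWarning, stacklevel=2
        )
    logs = np.log(values)
    obs = float(_ks_statistic_normal(logs, fit.mu, fit.sigma)[0])

    rng = np.random.default_rng(seed)
    draws = fit.mu + fit.sigma * rng.standard_normal((n_boot, values.size))
    boot_mu = draws.mean(axis=1)
    boot_sigma = draws.std(axis=1, ddof=1)
    boot = _ks_statistic_normal(draws, boot_mu, boot_sigma)
    pvalue = (1.0 + np.sum(boot >= obs)) / (n_boot + 1.0)
    return KsGofResult(statistic=obs, pvalue=float(pvalue), n_boot=n_boot)


# ----------------------------------------------------------------------
# model / results interface
# ----------------------------------------------------------------------
class CensoredLognormal:
    """Log-normal model for a left-censored dataset, estimated by
    semiparametric ROS.

    Parameters
    ----------
    dataset : CensoredDataset
        Records with censoring flags and per-record reporting limits.

    Examples
    --------
    >>> res = CensoredLognormal(dataset).fit()
    >>> res.params.mu, res.params.sigma
    >>> res.quantile(0.9)      # fitted 90th percentile, ppb
    >>> print(res.summary())
    """

    def __init__(self, dataset: CensoredDataset):
        if len(dataset) == 0:
            raise ValueError("empty dataset")
        self.dataset = dataset

    @classmethod
    def from_dataframe(cls, df, grouping: str = "") -> "CensoredLognormal":
        return cls(CensoredDataset.from_frame(df, grouping=grouping))

    def fit(self, gof_boot: int = 0, seed: int | None = None) -> "CensoredLognormalResults":
        """Impute censored records by ROS, then fit the log-normal to the
        completed data. ``gof_boot`` > 0 additionally runs the
        bootstrap KS goodness-of-fit test with that many replicates."""
        imputed = ros_impute(self.dataset)
        fit = fit_lognormal_mle(imputed.values)
        fit = LognormalFit(fit.mu, fit.sigma, fit.n, method="ros_regression")
        gof = None
        if gof_boot > 0:
            gof = ks_gof(imputed.values, fit, n_boot=gof_boot, seed=seed)
        return CensoredLognormalResults(self, imputed, fit, gof)


class CensoredLognormalResults:
    """Results of a :class:`CensoredLognormal` fit.

    Attributes
    ----------
    params : LognormalFit
        (mu, sigma) on the natural-log ppb scale.
    imputed_dataset : CensoredDataset
        The completed dataset; censored records carry ``imputed=True``.
    bse : tuple of float
        Normal-theory standard errors (sigma/sqrt(n), sigma/sqrt(2(n-1)))
        for (mu, sigma); they ignore imputation uncertainty and so
        understate the true spread when censoring is heavy.
    gof : KsGofResult or None
        Bootstrap KS goodness-of-fit, when requested.
    """

    def __init__(self, model, imputed_dataset, params, gof):
        self.model = model
        self.imputed_dataset = imputed_dataset
        self.params = params
        self.gof = gof
        n = params.n
        self.nobs = n
        self.bse = (
            params.sigma / np.sqrt(n),
            params.sigma / np.sqrt(2.0 * max(n - 1, 1)),
        )

    def quantile(self, p) -> float:
        return self.params.quantile(p)

    @property
    def stats(self) -> SummaryStats:
        return summary_stats(self.model.dataset)

    def summary(self) -> str:
        s = self.stats
        lines = [
            "Censored log-normal fit (semiparametric ROS)",
            "=" * 48,
            f"{'n':<28}{self.nobs:>20}",
            f"{'censored (BRL)':<28}{s.n_bdl:>14} ({100 * s.frac_bdl:.1f}%)",
            f"{'reporting limits (ppb)':<28}{str([float(x) for x in self.model.dataset.reporting_limits]):>20}",
            f"{'mu (log ppb)':<28}{self.params.mu:>14.4f} (se {self.bse[0]:.4f})",
            f"{'sigma (log ppb)':<28}{self.params.sigma:>14.4f} (se {self.bse[1]:.4f})",
            f"{'fitted median (ppb)':<28}{self.quantile(0.5):>20.3f}",
            f"{'fitted p90 (ppb)':<28}{self.quantile(0.9):>20.3f}",
        ]
        if s.p90_empirical is not None:
            lines.append(f"{'count-up p90 (ppb)':<28}{s.p90_empirical:>20.3f}")
        if self.gof is not None:
            lines.append(
                f"{'KS gof (boot)':<28}D={self.gof.statistic:.4f}, "
                f"p={self.gof.pvalue:.3f}".rjust(20)
            )
        return "\n".join(lines)

    def plot_cdf(self, ax=None, **kw):
        """Empirical CDF of the completed data (imputed points hollow)
        against the fitted log-normal CDF."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = self.imputed_dataset.values
        imput = np.array([r.imputed for r in self.imputed_dataset.records])
        order = np.argsort(v)
        ecdf = (np.arange(1, len(v) + 1)) / len(v)
        ax.scatter(v[order][~imput[order]], ecdf[~imput[order]], s=12, label="detects")
        ax.scatter(
            v[order][imput[order]], ecdf[imput[order]],
            s=12, facecolors="none", edgecolors="C0", label="imputed",
        )
        x = np.geomspace(v.min() / 2, v.max() * 2, 300)
        ax.plot(x, self.params.cdf(x), "r-", lw=1, label="fitted log-normal")
        ax.set_xscale("log")
        ax.set_xlabel("lead concentration (ppb)")
        ax.set_ylabel("cumulative probability")
        ax.legend()
        return ax
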