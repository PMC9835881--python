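"""ZIP-level aggregation and the self-selection trend.

In a customer-requested program, homes choose to be sampled. If
neighbourhoods with more above-detection results request sampling more
often (neighbours talking, local outreach), the program over-represents
affected areas. The assessment here aggregates records to ZIP level and
regresses the fraction of homes sampled on a quadratic in the fraction
of samples above the reporting limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .records import SampleRecord

__all__ = ["ZipSummary", "aggregate_by_zip", "quadratic_trend", "QuadraticTrend"]


@dataclass(frozen=True)
class ZipSummary:
    """Per-ZIP sampling summary.

    frac_above_rl = n_above_rl / n_samples;
    frac_sampled = n_samples / n_homes (capped at 1 with a warning when
    repeat sampling exceeds the housing stock).
    """

    zip: str
    n_samples: int
    n_above_rl: int
    n_homes: int
    frac_above_rl: float
    frac_sampled: float


def aggregate_by_zip(records, housing_counts: dict[str, int]) -> list[ZipSummary]:
    """One summary per observed ZIP code.

    Records without a ZIP label are dropped (with a logged count);
    ZIPs with samples but no housing count are excluded with a warning.
    Repeat samples from one block count as separate samples — home
    identity is unknowable behind block-level anonymisation, so no
    de-duplication is attempted.
    """
    records = list(records)
    by_zip: dict[str, list[SampleRecord]] = {}
    dropped = 0
    for rec in records:
        if rec.zip in (None, ""):
            dropped += 1
            continue
        by_zip.setdefault(rec.zip, []).append(rec)
    if dropped:
        warnings.warn(f"{dropped} record(s) without ZIP label dropped",
                      UserWarning, stacklevel=2)

    out: list[ZipSummary] = []
    for z in sorted(by_zip):
        recs = by_zip[z]
        if z not in housing_counts:
            warnings.warn(f"ZIP {z} has samples but no housing count; excluded",
                          UserWarning, stacklevel=2)
            continue
        n_homes = int(housing_counts[z])
        if n_homes <= 0:
            raise ValueError(f"housing count for ZIP {z} must be positive")
        n = len(recs)
        n_above = sum(1 for r in recs if not r.censored)
        frac_sampled = n / n_homes
        if frac_sampled > 1:
            warnings.warn(f"ZIP {z}: more samples than homes; frac_sampled capped at 1",
                          UserWarning, stacklevel=2)
            frac_sampled = 1.0
        out.append(
            ZipSummary(zip=z, n_samples=n, n_above_rl=n_above, n_homes=n_homes,
                       frac_above_rl=n_above / n, frac_sampled=frac_sampled)
        )
    return out


@dataclass(frozen=True)
class QuadraticTrend:
    """OLS fit of frac_sampled on (1, x, x^2), x = frac_above_rl."""

    coefficients: tuple[float, float, float]  # (intercept, linear, quadratic)
    r_squared: float
    tvalues: tuple[float, float, float]
    n: int
    weighted: bool

    def predict(self, x) -> np.ndarray:
        a, b, c = self.coefficients
        x = np.asarray(x, dtype=float)
        return a + b * x + c * x**2


def quadratic_trend(summaries: list[ZipSummary], weighted: bool = False) -> QuadraticTrend:
    """Fit the self-selection trend across ZIP summaries.

    Ordinary least squares of the fraction of homes sampled on a
    quadratic in the fraction of samples above the reporting limit;
    ``weighted=True`` instead weights ZIPs by their sample counts (WLS).

    Raises
    ------
    ValueError
        Fewer than 4 ZIPs, or fewer than 3 distinct x values
        (rank-deficient design).
    """
    if len(summaries) < 4:
        raise ValueError("quadratic trend needs >= 4 ZIP summaries")
    x = np.array([s.frac_above_rl for s in summaries])
    y = np.array([s.frac_sampled for s in summaries])
    if len(np.unique(x)) < 3:
        raise ValueError("rank-deficient design: need >= 3 distinct frac_above_rl")
    X = sm.add_constant(np.column_stack([x, x**2]))
    if weighted:
        w = np.array([s.n_samples for s in summaries], dtype=float)
        res = sm.WLS(y, X, weights=w).fit()
    else:
        res = sm.OLS(y, X).fit()
    return QuadraticTrend(
        coefficients=tuple(float(c) for c in res.params),
        r_squared=float(res.rsquared),
        tvalues=tuple(float(t) for t in res.tvalues),
        n=len(summaries),
        weighted=weighted,
    )


def summaries_to_frame(summaries: list[ZipSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
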