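"""Period/treatment grouping and two-sample distribution comparisons.

Sampling records are grouped either by calendar year or by treatment
period around the introduction of orthophosphate corrosion control
(April 2019). The treatment grouping excludes records whose timing
relative to the treatment change cannot be confirmed: regulatory (LCR)
rounds reported June 2019 (collected January-May 2019) and
customer-requested samples analysed April-May 2019.

Groups are compared pairwise with the two-sample Kolmogorov-Smirnov
test (distribution shape) and the Wilcoxon rank-sum test (mean rank,
with midrank tie correction — heavy ties are expected because censored
values sit at their reporting limits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy import stats

from .records import CensoredDataset, SampleRecord

__all__ = [
    "GroupingScheme",
    "group_records",
    "ks_two_sample",
    "wilcoxon_rank_sum",
    "KsTwoSampleResult",
    "RankSumResult",
    "pairwise_tests",
]

EXCLUDED = "excluded"

_TEST_CAVEAT = (
    "Samples share temporal/spatial structure (repeat requests, common "
    "water chemistry), so the independence assumption is approximate; "
    "interpret p-values as broad-scale indications."
)

_MONTHS = {
    m.lower(): i
    for i, m in enumerate(
        ["January", "February", "March", "April", "May", "June", "July",
         "August", "September", "October", "November", "December"],
        start=1,
    )
}
_MONTHS.update({m[:3].lower(): i for m, i in list(_MONTHS.items())})

# orthophosphate dosing began April 2019
_TREATMENT_START = date(2019, 4, 1)
_CUSTOMER_EXCL_END = date(2019, 5, 31)
_POST_END = date(2020, 6, 30)
# LCR reporting periods by treatment group
_LCR_PRE = {(6, 2016), (12, 2016), (6, 2017), (12, 2017), (6, 2018), (12, 2018)}
_LCR_POST = {(12, 2019), (6, 2020)}
_LCR_EXCLUDED = {(6, 2019)}


@dataclass(frozen=True)
class GroupingScheme:
    """How records map to analysis groups.

    scheme : {"annual", "treatment"}
    pre_label, post_label : group names used by the treatment scheme.
    """

    scheme: str = "annual"
    pre_label: str = "pre_ortho"
    post_label: str = "post_ortho"

    def __post_init__(self) -> None:
        if self.scheme not in ("annual", "treatment"):
            raise ValueError("scheme must be 'annual' or 'treatment'")


def _parse_lcr_period(label: str) -> tuple[int, int] | None:
    """'June 2016' / 'Dec 2016' -> (month, year), else None."""
    parts = label.replace(",", " ").split()
    if len(parts) != 2:
        return None
    month = _MONTHS.get(parts[0].lower())
    try:
        year = int(parts[1])
    except ValueError:
        return None
    return (month, year) if month else None


def _parse_customer_date(label: str) -> date | None:
    try:
        return date.fromisoformat(label.strip())
    except ValueError:
        return None


def _group_of(record: SampleRecord, scheme: GroupingScheme) -> str | None:
    """Group name for one record; None marks an unparseable period."""
    if record.program == "lcr":
        my = _parse_lcr_period(record.period)
        if my is None:
            return None
        if scheme.scheme == "annual":
            return str(my[1])
        if my in _LCR_PRE:
            return scheme.pre_label
        if my in _LCR_POST:
            return scheme.post_label
        return EXCLUDED  # June 2019 (collection timing unconfirmed) etc.
    d = _parse_customer_date(record.period)
    if d is None:
        return None
    if scheme.scheme == "annual":
        return str(d.year)
    if d < _TREATMENT_START:
        return scheme.pre_label
    if d <= _CUSTOMER_EXCL_END:
        return EXCLUDED  # analysed April-May 2019
    if d <= _POST_END:
        return scheme.post_label
    return EXCLUDED


def group_records(
    records, scheme: GroupingScheme = GroupingScheme()
) -> dict[str, CensoredDataset]:
    """Partition records into analysis groups.

    Returns a map group-name -> :class:`CensoredDataset`; records
    excluded by the treatment scheme, or with unparseable period labels
    (warned per record), land in the ``"excluded"`` bucket. The
    partition is exhaustive and mutually exclusive by construction and
    re-asserted before returning.
    """
    records = list(records)
    buckets: dict[str, list[SampleRecord]] = {}
    for rec in records:
        g = _group_of(rec, scheme)
        if g is None:
            warnings.warn(
                f"unparseable period label {rec.period!r}; record excluded",
                UserWarning,
                stacklevel=2,
            )
            g = EXCLUDED
        buckets.setdefault(g, []).append(rec)
    assert sum(len(v) for v in buckets.values()) == len(records)
    return {g: CensoredDataset(v, grouping=g) for g, v in sorted(buckets.items())}


# ----------------------------------------------------------------------
# two-sample tests
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class KsTwoSampleResult:
    statistic: float
    pvalue: float
    warning: str = _TEST_CAVEAT


@dataclass(frozen=True)
class RankSumResult:
    """Wilcoxon rank-sum with midrank tie correction.

    ``statistic`` is the rank sum of the first sample; ``variance`` the
    tie-corrected null variance used by the normal approximation.
    """

    statistic: float
    zstat: float
    pvalue: float
    mean: float
    variance: float
    warning: str = _TEST_CAVEAT


def ks_two_sample(a, b) -> KsTwoSampleResult:
    """Two-sample KS test: maximum gap between the two empirical CDFs,
    with the asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("both samples need n >= 5")
    res = stats.ks_2samp(a, b, method="asymp")
    return KsTwoSampleResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


def wilcoxon_rank_sum(a, b) -> RankSumResult:
    """Wilcoxon rank-sum test with midranks and tie-corrected variance.

    Pooled observations receive midranks; the statistic is the rank sum
    W of the first sample. Under the null its mean is n1 (N+1)/2 and its
    variance

        n1 n2 / 12 * [ (N+1) - sum(t^3 - t) / (N (N-1)) ]

    summing over tie groups of size t. The two-sided p-value uses the
    normal approximation (no continuity correction, so the variance is
    exactly the permutation variance of the midrank statistic). With all
    pooled values tied the test is degenerate: a warning is emitted and
    p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 3 or n2 < 3:
        raise ValueError("both samples need n >= 3")
    pooled = np.concatenate([a, b])
    N = n1 + n2
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    mean = n1 * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (N * (N - 1))
    variance = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if variance <= 0:
        warnings.warn("all pooled values tied: degenerate rank-sum test",
                      UserWarning, stacklevel=2)
        return RankSumResult(statistic=w, zstat=0.0, pvalue=1.0,
                             mean=mean, variance=0.0)
    z = (w - mean) / np.sqrt(variance)
    p = 2.0 * stats.norm.sf(abs(z))
    return RankSumResult(statistic=w, zstat=float(z), pvalue=float(min(p, 1.0)),
                         mean=mean, variance=float(variance))


def pairwise_tests(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise KS and rank-sum tests over a map group-name -> values.

    Returns a long-format table (group_a, group_b, ks_stat, ks_p,
    ranksum_z, ranksum_p); raw (uncorrected) pairwise p-values.
    """
    names = sorted(groups)
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            ks = ks_two_sample(groups[ga], groups[gb])
            rs = wilcoxon_rank_sum(groups[ga], groups[gb])
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "ks_stat": ks.statistic,
                    "ks_p": ks.pvalue,
                    "ranksum_z": rs.zstat,
                    "ranksum_p": rs.pvalue,
                }
            )
    return pd.DataFrame(rows)
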