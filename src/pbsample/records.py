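"""Core containers for home-tap lead measurements with left-censoring metadata.

A laboratory reports a tap sample either as a measured concentration (a
"detect") or as below its reporting limit (BRL, a left-censored
observation). Because multiple laboratories with different reporting
limits (1-4 ppb) analyse samples within one program, a dataset generally
carries several distinct censoring thresholds at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["SampleRecord", "CensoredDataset"]


@dataclass(frozen=True)
class SampleRecord:
    """One home-tap lead measurement.

    Parameters
    ----------
    reported_value : float
        Concentration in ppb. For a censored record this is the reporting
        limit (the sentinel the laboratory prints as "<RL").
    censored : bool
        True when the laboratory reported the sample below its reporting
        limit.
    reporting_limit : float
        The reporting limit (ppb) of the laboratory that analysed this
        sample.
    program : str
        Sampling program: ``"lcr"`` (regulatory compliance sampling at
        Tier I sites) or ``"customer"`` (customer-requested sampling).
    period : str
        For LCR records a reporting-period label such as ``"June 2016"``;
        for customer records the ISO-8601 analysis date.
    zip : str or None
        Coarse location (ZIP code), when available.
    block : str or None
        Street-block string, when available.
    true_value : float or None
        The latent concentration, known only for synthetic records.
        Retained to enable parameter-recovery tests; file writers strip
        it by default.
    imputed : bool
        True once a censored record's value has been replaced by a
        model-based imputation.
    """

    reported_value: float
    censored: bool
    reporting_limit: float
    program: str = "customer"
    period: str = ""
    zip: str | None = None
    block: str | None = None
    true_value: float | None = None
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.reporting_limit <= 0:
            raise ValueError("reporting_limit must be positive")
        if not self.censored and self.reported_value <= 0:
            raise ValueError("detected concentration must be positive")
        if self.program not in ("lcr", "customer"):
            raise ValueError(f"unknown program {self.program!r}")

    @property
    def value(self) -> float:
        """Concentration used in computations: the reported value for a
        detect, the reporting limit for an (un-imputed) censored record."""
        return self.reported_value


class CensoredDataset:
    """A grouped collection of :class:`SampleRecord` sharing one analysis
    grouping (a year or a treatment period).

    Provides array views of the records so the numerical routines can
    operate on numpy arrays, and pandas round-tripping for IO.
    """

    def __init__(self, records: Iterable[SampleRecord], grouping: str = ""):
        self.records: list[SampleRecord] = list(records)
        self.grouping = grouping

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> SampleRecord:
        return self.records[i]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CensoredDataset)
            and self.grouping == other.grouping
            and self.records == other.records
        )

    def __repr__(self) -> str:
        return (
            f"<CensoredDataset {self.grouping!r}: n={len(self)}, "
            f"{self.n_censored} censored, limits={list(self.reporting_limits)}>"
        )

    # ------------------------------------------------------------------
    # array views
    # ------------------------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        """Reported concentrations (ppb); censored entries at their RL."""
        return np.array([r.reported_value for r in self.records], dtype=float)

    @property
    def censored_mask(self) -> np.ndarray:
        return np.array([r.censored for r in self.records], dtype=bool)

    @property
    def limits(self) -> np.ndarray:
        """Per-record reporting limits (ppb)."""
        return np.array([r.reporting_limit for r in self.records], dtype=float)

    @property
    def reporting_limits(self) -> np.ndarray:
        """Sorted unique reporting limits present in the dataset."""
        return np.unique(self.limits) if self.records else np.array([])

    @property
    def n_censored(self) -> int:
        return int(self.censored_mask.sum()) if self.records else 0

    @property
    def detects(self) -> np.ndarray:
        """Observed (uncensored) concentrations."""
        v = self.values
        return v[~self.censored_mask] if self.records else v

    @property
    def true_values(self) -> np.ndarray | None:
        """Latent concentrations, when every record carries one (synthetic
        data); None otherwise."""
        tv = [r.true_value for r in self.records]
        if any(t is None for t in tv):
            return None
        return np.array(tv, dtype=float)

    # ------------------------------------------------------------------
    # construction / conversion
    # ------------------------------------------------------------------
    def with_records(self, records: Sequence[SampleRecord]) -> "CensoredDataset":
        return CensoredDataset(records, grouping=self.grouping)

    def to_frame(self, include_true: bool = False) -> pd.DataFrame:
        cols = {
            "reported_value": [r.reported_value for r in self.records],
            "censored": [r.censored for r in self.records],
            "reporting_limit": [r.reporting_limit for r in self.records],
            "program": [r.program for r in self.records],
            "period": [r.period for r in self.records],
            "zip": [r.zip for r in self.records],
            "block": [r.block for r in self.records],
            "imputed": [r.imputed for r in self.records],
        }
        if include_true:
            cols["true_value"] = [r.true_value for r in self.records]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, grouping: str = "") -> "CensoredDataset":
        recs = []
        has_true = "true_value" in df.columns
        for row in df.itertuples(index=False):
            recs.append(
                SampleRecord(
                    reported_value=float(row.reported_value),
                    censored=bool(row.censored),
                    reporting_limit=float(row.reporting_limit),
                    program=str(row.program),
                    period=str(row.period),
                    zip=None if pd.isna(row.zip) else str(row.zip),
                    block=None if pd.isna(row.block) else str(row.block),
                    true_value=(
                        float(row.true_value)
                        if has_true and not pd.isna(row.true_value)
                        else None
                    ),
                    imputed=bool(getattr(row, "imputed", False)),
                )
            )
        return cls(recs, grouping=grouping)


def replace_record(record: SampleRecord, **kw) -> SampleRecord:
    """dataclasses.replace wrapper kept importable for internal use."""
    return replace(record, **kw)
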