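"""CSV dialects, pipeline configuration, and the end-to-end driver.

Two CSV dialects mirror the column semantics of the two public
program spreadsheets:

``lcr``
    Columns ``block, period, lead_ppb, reporting_limit_ppb``; a
    censored sample is written as a ``<RL`` token in ``lead_ppb``
    (e.g. ``<2``).
``customer``
    Columns ``block, zip, analysis_date, lead_ppb, below_rl,
    reporting_limit_ppb``; a censored sample has ``below_rl=True`` and
    ``lead_ppb`` equal to the reporting limit.

Malformed rows are collected into an error report, never silently
dropped. The pipeline driver sequences the analysis stages — impute ->
fit -> mixture -> Monte Carlo -> compare -> spatial — writing CSV
outputs plus a machine-readable run manifest; all randomness flows
from the single configuration seed via per-stage spawned seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .censored import fit_lognormal_mle, ros_impute, summary_stats
from .comparisons import EXCLUDED, GroupingScheme, group_records, pairwise_tests
from .compliance import MonteCarloConfig, exceedance_probability, simulate_p90_distribution
from .mixture import LognormalMixture, save_mixture
from .records import CensoredDataset, SampleRecord
from .spatial import aggregate_by_zip, quadratic_trend, summaries_to_frame
from .synthetic import PRESET_NAMES, generate_cohort, preset

__all__ = [
    "FormatError",
    "PipelineError",
    "PipelineConfig",
    "read_samples_csv",
    "write_samples_csv",
    "read_housing_counts",
    "run_pipeline",
]

logger = logging.getLogger("pbsample")


class FormatError(ValueError):
    """A required column is missing or a file is structurally invalid."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


# ----------------------------------------------------------------------
# sample CSV dialects
# ----------------------------------------------------------------------
_REQUIRED = {
    "lcr": ["period", "lead_ppb"],
    "customer": ["analysis_date", "lead_ppb", "below_rl", "reporting_limit_ppb"],
}


def read_samples_csv(path, dialect: str) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Read one program spreadsheet.

    Returns (records, error_report); the report has one row per
    malformed input row (with its index and the reason).
    """
    if dialect not in _REQUIRED:
        raise ValueError("dialect must be 'lcr' or 'customer'")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED[dialect] if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    records: list[SampleRecord] = []
    errors: list[dict] = []
    for i, row in df.iterrows():
        try:
            records.append(_parse_row(row, dialect))
        except (ValueError, KeyError) as exc:
            errors.append({"row": int(i), "reason": str(exc)})
    return records, pd.DataFrame(errors, columns=["row", "reason"])


def _parse_row(row, dialect: str) -> SampleRecord:
    block = row.get("block") or None
    if dialect == "lcr":
        token = str(row["lead_ppb"]).strip()
        if token.startswith("<"):
            rl = float(token[1:])
            value, censored = rl, True
        else:
            value, censored = float(token), False
            rl_str = str(row.get("reporting_limit_ppb", "")).strip()
            rl = float(rl_str) if rl_str else 1.0
        if value < 0:
            raise ValueError(f"negative concentration {value}")
        return SampleRecord(
            reported_value=value, censored=censored, reporting_limit=rl,
            program="lcr", period=str(row["period"]).strip(), block=block,
        )
    value = float(str(row["lead_ppb"]).strip())
    if value < 0:
        raise ValueError(f"negative concentration {value}")
    censored = str(row["below_rl"]).strip().lower() in ("true", "1", "yes")
    rl = float(str(row["reporting_limit_ppb"]).strip())
    return SampleRecord(
        reported_value=rl if censored else value,
        censored=censored, reporting_limit=rl, program="customer",
        period=str(row["analysis_date"]).strip(),
        zip=(row.get("zip") or None), block=block,
    )


def write_samples_csv(
    records, path, dialect: str, include_true: bool = False,
    include_imputed: bool = False,
) -> None:
    """Write records in one of the two dialects.

    The hidden ``true_value`` of synthetic records is stripped unless
    ``include_true``; ``include_imputed`` adds the imputed-flag column so
    consumers can distinguish observed from imputed values.
    """
    rows = []
    for r in records:
        if dialect == "lcr":
            row = {
                "block": r.block or "",
                "period": r.period,
                "lead_ppb": (
                    f"<{r.reporting_limit:g}"
                    if r.censored and not r.imputed
                    else repr(float(r.reported_value))
                ),
                "reporting_limit_ppb": repr(float(r.reporting_limit)),
            }
        elif dialect == "customer":
            row = {
                "block": r.block or "",
                "zip": r.zip or "",
                "analysis_date": r.period,
                "lead_ppb": repr(float(r.reported_value)),
                "below_rl": r.censored,
                "reporting_limit_ppb": repr(float(r.reporting_limit)),
            }
        else:
            raise ValueError("dialect must be 'lcr' or 'customer'")
        if include_imputed:
            row["imputed"] = r.imputed
        if include_true:
            row["true_value"] = "" if r.true_value is None else repr(float(r.true_value))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_housing_counts(path) -> dict[str, int]:
    """Two-column CSV (zip, n_homes) -> mapping."""
    df = pd.read_csv(path, dtype={"zip": str})
    for col in ("zip", "n_homes"):
        if col not in df.columns:
            raise FormatError(f"missing required column(s): {col}")
    return {str(z): int(n) for z, n in zip(df["zip"], df["n_homes"])}


# ----------------------------------------------------------------------
# pipeline configuration
# ----------------------------------------------------------------------
@dataclass
class PipelineConfig:
    """Configuration for one end-to-end run.

    Either ``presets`` (named synthetic cohorts, each its own group) or
    ``inputs`` (paths + dialects, grouped by ``grouping``) must be set.
    """

    presets: tuple[str, ...] = ()
    preset_n: int | None = None  # override preset cohort sizes
    inputs: tuple[tuple[str, str], ...] = ()  # (path, dialect)
    grouping: str = "treatment"
    candidate_ks: tuple[int, ...] = (1, 2)
    n_draw: int = 150
    n_rep: int = 10000
    action_level: float = 15.0
    housing_counts: str | None = None
    out_dir: str = "pbsample_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.presets and not self.inputs:
            raise ValueError("config needs a generator preset or input files")
        for name in self.presets:
            if name not in PRESET_NAMES:
                raise ValueError(f"unknown preset {name!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["presets"] = tuple(d.get("presets", ()))
        d["inputs"] = tuple(tuple(x) for x in d.get("inputs", ()))
        d["candidate_ks"] = tuple(d.get("candidate_ks", (1, 2)))
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self.to_dict()), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


# ----------------------------------------------------------------------
# driver
# ----------------------------------------------------------------------
def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Writes, under ``config.out_dir``: per-group summaries and fits,
    imputed datasets, mixture files and the BIC table, exceedance
    curves, the pairwise test matrix, the ZIP trend (when spatial
    inputs exist), and ``manifest.json``. Outputs are byte-identical
    for identical config and seed. Returns the manifest dictionary.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seed = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(["generate", "mixture", "mc"], ss.spawn(3))
    }
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _jsonable(config.to_dict()),
        "config_hash": config.config_hash(),
        "stage_seeds": stage_seed,
        "outputs": [],
        "counts": {},
    }

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False)
        manifest["outputs"].append(name)

    # ---- stage: load / generate -------------------------------------
    stage = "load"
    try:
        groups: dict[str, CensoredDataset] = {}
        all_records: list[SampleRecord] = []
        if config.presets:
            gen_ss = np.random.SeedSequence(stage_seed["generate"]).spawn(len(config.presets))
            for name, child in zip(config.presets, gen_ss):
                cfg = preset(name, n_samples=config.preset_n,
                             seed=int(child.generate_state(1)[0] % (2**31)))
                ds = generate_cohort(cfg)
                groups[name] = ds
                all_records.extend(ds.records)
                logger.info("generated preset %s: %d records (%d censored)",
                            name, len(ds), ds.n_censored)
        else:
            for path, dialect in config.inputs:
                recs, errs = read_samples_csv(path, dialect)
                all_records.extend(recs)
                if len(errs):
                    emit(f"errors_{Path(path).stem}.csv", errs)
                logger.info("read %s (%s): %d records, %d malformed",
                            path, dialect, len(recs), len(errs))
            groups = {
                g: ds
                for g, ds in group_records(all_records, GroupingScheme(config.grouping)).items()
                if g != EXCLUDED
            }
        manifest["counts"]["records"] = len(all_records)
        manifest["counts"]["groups"] = {g: len(ds) for g, ds in groups.items()}
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: impute + single fits --------------------------------
    stage = "impute"
    fits_rows, summary_rows = [], []
    imputed_groups: dict[str, CensoredDataset] = {}
    try:
        for g, ds in groups.items():
            s = summary_stats(ds)
            summary_rows.append(
                {"group": g, "n": s.n, "n_bdl": s.n_bdl, "frac_bdl": s.frac_bdl,
                 "median_ppb": "below RL" if s.median_below_rl else s.median,
                 "countup_p90_ppb": s.p90_empirical}
            )
            imp = ros_impute(ds)
            imputed_groups[g] = imp
            fit = fit_lognormal_mle(imp.values)
            fits_rows.append(
                {"group": g, "mu": fit.mu, "sigma": fit.sigma, "n": fit.n,
                 "fitted_p90_ppb": fit.quantile(0.9)}
            )
            write_samples_csv(imp.records, out / f"imputed_{g}.csv",
                              dialect="customer" if imp.records[0].program == "customer" else "lcr",
                              include_imputed=True)
            manifest["outputs"].append(f"imputed_{g}.csv")
        emit("group_summary.csv", pd.DataFrame(summary_rows))
        emit("lognormal_fits.csv", pd.DataFrame(fits_rows))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: mixture ---------------------------------------------
    stage = "mixture"
    mixtures = {}
    bic_rows = []
    try:
        for g, imp in imputed_groups.items():
            if len(imp) < 10 * max(config.candidate_ks):
                logger.info("group %s too small for mixture fitting; skipped", g)
                continue
            res = LognormalMixture(imp.values, k=config.candidate_ks).fit(
                seed=stage_seed["mixture"]
            )
            mixtures[g] = res
            save_mixture(res, out / f"mixture_{g}.txt")
            manifest["outputs"].append(f"mixture_{g}.txt")
            for _, row in res.bic_table.iterrows():
                bic_rows.append({"group": g, **row.to_dict()})
        if bic_rows:
            emit("bic_table.csv", pd.DataFrame(bic_rows))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: monte carlo -----------------------------------------
    stage = "mc"
    try:
        exceed_rows = []
        for g, res in mixtures.items():
            mc = MonteCarloConfig(n_draw=config.n_draw, n_rep=config.n_rep,
                                  seed=stage_seed["mc"])
            curve = simulate_p90_distribution(res.mixture, mc)
            emit(f"exceedance_{g}.csv", curve.to_frame())
            exceed_rows.append(
                {"group": g,
                 "p_exceed_action_level": exceedance_probability(curve, config.action_level),
                 "action_level_ppb": config.action_level}
            )
        if exceed_rows:
            emit("exceedance_summary.csv", pd.DataFrame(exceed_rows))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: comparisons -----------------------------------------
    stage = "compare"
    try:
        usable = {g: imp.values for g, imp in imputed_groups.items() if len(imp) >= 5}
        if len(usable) >= 2:
            emit("pairwise_tests.csv", pairwise_tests(usable))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: spatial ---------------------------------------------
    stage = "spatial"
    try:
        with_zip = [r for r in all_records if r.zip]
        if config.housing_counts and with_zip:
            counts = read_housing_counts(config.housing_counts)
            summaries = aggregate_by_zip(with_zip, counts)
            emit("zip_summary.csv", summaries_to_frame(summaries))
            if len(summaries) >= 4:
                trend = quadratic_trend(summaries)
                emit("zip_trend.csv", pd.DataFrame([{
                    "intercept": trend.coefficients[0],
                    "linear": trend.coefficients[1],
                    "quadratic": trend.coefficients[2],
                    "r_squared": trend.r_squared,
                    "n_zips": trend.n,
                }]))
        else:
            logger.info("spatial stage skipped (no ZIP labels or housing counts)")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
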