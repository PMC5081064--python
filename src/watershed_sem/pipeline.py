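"""Staged analysis battery and behavioural preprocessing.

Runs the complete watershed analysis on any sample moments: the measurement
model, the processing-speed and tract dimensionality stages, the MIMIC model
with its constrained competitors, the full three-level model with its
competitors, the covariate-adjusted variant, the inverted-hierarchy AIC
contest, the exhaustive tract-subset contests and a modification-index scan —
recording fit verdicts against the configured index bands at every stage.
Failed stages are recorded and the battery continues; the staged narrative
requires all stages even when early ones fit poorly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .builders import (
    DEFAULT_CONFIG,
    WatershedConfig,
    build_full_watershed,
    build_inverted_watershed,
    build_measurement_model,
    build_mimic,
    build_ps_factor_models,
    enumerate_tract_subsets,
    make_variant,
)
from .estimator import (
    ComparisonResult,
    FitResult,
    SampleMoments,
    compare_nested,
    fit_model,
    modification_indices,
)

__all__ = [
    "FitThresholds",
    "BatteryReport",
    "preprocess_behavioural",
    "residualize_on_covariate",
    "run_battery",
    "verdict",
]


@dataclass(frozen=True)
class FitThresholds:
    """Good/acceptable bands for the three fit indices."""

    rmsea_good: float = 0.05
    rmsea_acceptable: float = 0.08
    cfi_good: float = 0.97
    cfi_acceptable: float = 0.95
    srmr_good: float = 0.05
    srmr_acceptable: float = 0.10

    def __post_init__(self) -> None:
        if not (self.rmsea_good < self.rmsea_acceptable and self.srmr_good < self.srmr_acceptable):
            raise ValueError("good bounds must be tighter than acceptable bounds")
        if not self.cfi_good > self.cfi_acceptable:
            raise ValueError("good CFI bound must exceed the acceptable bound")


def verdict(fit: FitResult, thresholds: FitThresholds = FitThresholds()) -> dict[str, str]:
    """Classify each index of a fit as good / acceptable / poor."""
    t = thresholds
    out: dict[str, str] = {}
    idx = fit.indices
    if idx is None:
        return {"rmsea": "n/a", "cfi": "n/a", "srmr": "n/a"}

    def band(value: float, good: float, acceptable: float, larger_better: bool) -> str:
        if not np.isfinite(value):
            return "n/a"
        if larger_better:
            return "good" if value > good else ("acceptable" if value >= acceptable else "poor")
        return "good" if value < good else ("acceptable" if value <= acceptable else "poor")

    out["rmsea"] = band(idx.rmsea, t.rmsea_good, t.rmsea_acceptable, False)
    out["cfi"] = band(idx.cfi, t.cfi_good, t.cfi_acceptable, True)
    out["srmr"] = band(idx.srmr, t.srmr_good, t.srmr_acceptable, False)
    return out


# ---------------------------------------------------------------------------
# behavioural preprocessing
# ---------------------------------------------------------------------------


def preprocess_behavioural(
    raw: pd.DataFrame,
    speed_columns: list[str] | None = None,
    sd_limit: float = 4.0,
    restandardize: bool = True,
) -> pd.DataFrame:
    """Reaction-time preprocessing and outlier trimming.

    Columns named in ``speed_columns`` are transformed reciprocal (1/RT), then
    log, then z-scored, so larger scores mean speedier/more consistent
    responding; the remaining columns are z-scored.  Any value beyond
    ``sd_limit`` standard deviations from its column mean is marked, and
    subjects with a marked or missing value anywhere are dropped
    (complete-case).  Surviving columns are re-standardized by default.
    """
    speed_columns = list(speed_columns or [])
    out = raw.copy()
    for col in speed_columns:
        if col not in out.columns:
            raise KeyError(f"speed column {col!r} not in table")
        vals = out[col].to_numpy(dtype=float)
        if np.nanmin(vals) <= 0:
            raise ValueError(f"column {col!r} has nonpositive reaction times")
        out[col] = np.log(1.0 / vals)

    z = pd.DataFrame(index=out.index)
    for col in out.columns:
        vals = out[col].to_numpy(dtype=float)
        sd = np.nanstd(vals, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        z[col] = (vals - np.nanmean(vals)) / sd

    marked = z.abs() > sd_limit
    keep = ~(marked.any(axis=1) | z.isna().any(axis=1))
    trimmed = z.loc[keep]
    n_dropped = int((~keep).sum())
    if restandardize and n_dropped:
        trimmed = (trimmed - trimmed.mean()) / trimmed.std(ddof=1)
    trimmed.attrs["n_dropped"] = n_dropped
    trimmed.attrs["frac_marked_values"] = float(marked.to_numpy().mean())
    return trimmed


def residualize_on_covariate(
    data: pd.DataFrame, covariate: str, targets: list[str] | None = None
) -> pd.DataFrame:
    """Replace each target column by its re-standardized residual from a
    univariate linear projection on the covariate (e.g. age-corrected tracts)."""
    if covariate not in data.columns:
        raise KeyError(f"covariate {covariate!r} not in table")
    x = data[covariate].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError("covariate is constant")
    xc = x - x.mean()
    out = data.copy()
    for col in targets if targets is not None else [c for c in data.columns if c != covariate]:
        y = data[col].to_numpy(dtype=float)
        beta = float(xc @ (y - y.mean())) / float(xc @ xc)
        resid = y - y.mean() - beta * xc
        sd = resid.std(ddof=1)
        if sd < 1e-12:
            warnings.warn(f"column {col!r} collinear with {covariate!r}; residual has zero variance")
            out[col] = resid
        else:
            out[col] = resid / sd
    return out


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------


@dataclass
class StageRecord:
    name: str
    model_syntax: str
    fit: FitResult | None
    verdict: dict[str, str] = field(default_factory=dict)
    error: str | None = None


@dataclass
class BatteryReport:
    config: WatershedConfig
    thresholds: FitThresholds
    stages: dict[str, StageRecord] = field(default_factory=dict)
    comparisons: dict[str, ComparisonResult] = field(default_factory=dict)
    subset_contests: pd.DataFrame | None = None
    subset_contests_covariate: pd.DataFrame | None = None
    modification_scan: list = field(default_factory=list)

    def stage_fit(self, name: str) -> FitResult:
        rec = self.stages[name]
        if rec.fit is None:
            raise RuntimeError(f"stage {name!r} failed: {rec.error}")
        return rec.fit


def _subset_contest_frame(
    data: SampleMoments, configs: list[WatershedConfig], fit_options: dict
) -> pd.DataFrame:
    rows = []
    for cfg in configs:
        sub = data.select(cfg.observed_names())
        water = fit_model(build_full_watershed(cfg), sub, **fit_options)
        inv = fit_model(build_inverted_watershed(cfg), sub, **fit_options)
        rows.append(
            {
                "tracts": ",".join(cfg.wm_tracts),
                "aic_watershed": water.aic,
                "aic_inverted": inv.aic,
                "delta_aic": inv.aic - water.aic,  # positive favours the watershed direction
                "watershed_wins": inv.aic > water.aic,
            }
        )
    return pd.DataFrame(rows)


def run_battery(
    data: SampleMoments,
    config: WatershedConfig = DEFAULT_CONFIG,
    *,
    thresholds: FitThresholds = FitThresholds(),
    subset_contests: bool = True,
    subset_k: int = 6,
    modification_scan: bool = True,
    strongest_ps: str = "CRTspeed",
    strongest_tract: str = "FMin",
    fit_options: dict | None = None,
) -> BatteryReport:
    """Execute the staged battery on sample moments and return the report.

    The "strongest path" sources of the constrained competitors are inputs,
    keeping the battery deterministic.  Identical inputs and configuration
    yield an identical report.
    """
    fit_options = dict(fit_options or {})
    report = BatteryReport(config=config, thresholds=thresholds)

    def stage(name: str, spec) -> FitResult | None:
        syntax = spec.to_syntax()
        try:
            fit = fit_model(spec, data, **fit_options)
        except Exception as exc:  # record and continue
            report.stages[name] = StageRecord(name, syntax, None, error=str(exc))
            return None
        report.stages[name] = StageRecord(name, syntax, fit, verdict(fit, thresholds))
        return fit

    # 1. measurement model for fluid intelligence
    stage("measurement", build_measurement_model(list(config.fi_indicators), config.fi_name))

    # 2. processing-speed dimensionality
    for name, spec in build_ps_factor_models(config).items():
        stage(f"ps_{name}", spec)

    # 3. tract-level dimensionality
    stage("wm_single", build_measurement_model(list(config.wm_tracts), "WM"))

    # 4. MIMIC model and its constrained competitors
    mimic = build_mimic(config)
    fit_mimic = stage("mimic", mimic)
    for kind, kwargs in (
        ("zero_paths", {}),
        ("equal_paths", {}),
        ("strongest_only", {"source": strongest_ps}),
    ):
        variant = make_variant(mimic, kind, config=config, block="ps_fi", **kwargs)
        fit_v = stage(f"mimic_{kind}", variant)
        if fit_mimic is not None and fit_v is not None:
            report.comparisons[f"mimic_vs_{kind}"] = compare_nested(
                fit_v, fit_mimic, restricted_id=f"mimic_{kind}", full_id="mimic"
            )

    # 5. full watershed model and its competitors
    from dataclasses import replace as _replace

    base_cfg = config if not config.covariates else _replace(config, covariates=())
    full = build_full_watershed(base_cfg)
    fit_full = stage("watershed", full)
    for kind, kwargs in (
        ("zero_paths", {}),
        ("strongest_only", {"source": strongest_tract}),
        ("source_specific", {}),
        ("target_specific", {}),
    ):
        variant = make_variant(full, kind, config=base_cfg, block="wm_ps", **kwargs)
        fit_v = stage(f"watershed_{kind}", variant)
        if fit_full is not None and fit_v is not None:
            report.comparisons[f"watershed_vs_{kind}"] = compare_nested(
                fit_v, fit_full, restricted_id=f"watershed_{kind}", full_id="watershed"
            )

    # 6. covariate-adjusted model
    if config.covariates:
        stage("watershed_covariates", build_full_watershed(config))

    # 7. inverted-hierarchy AIC contest
    inverted = build_inverted_watershed(base_cfg)
    fit_inv = stage("inverted", inverted)
    if fit_full is not None and fit_inv is not None:
        report.comparisons["watershed_vs_inverted"] = ComparisonResult(
            delta_T=fit_inv.T_ml - fit_full.T_ml,
            delta_df=fit_inv.df - fit_full.df,
            p_value=float("nan"),  # not nested; AIC decides
            delta_aic=fit_inv.aic - fit_full.aic,
            preferred="watershed" if fit_full.aic < fit_inv.aic else "inverted",
            restricted_id="inverted",
            full_id="watershed",
        )

    # 8. exhaustive tract-subset contests
    if subset_contests:
        configs = enumerate_tract_subsets(list(config.wm_tracts), subset_k, base_cfg)
        report.subset_contests = _subset_contest_frame(data, configs, fit_options)
        if config.covariates:
            cov_configs = enumerate_tract_subsets(list(config.wm_tracts), subset_k, config)
            report.subset_contests_covariate = _subset_contest_frame(
                data, cov_configs, fit_options
            )

    # 9. modification-index scan of the full model
    if modification_scan and fit_full is not None:
        report.modification_scan = modification_indices(fit_full)

    return report
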