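"""Readers, writers and run configuration.

File dialects are plain delimited text: a covariance matrix is a square
numeric block with a header row and an index column of variable names (an
optional ``# N=...`` comment line carries the sample size); raw data are one
row per subject with a header of variable names.  Reports are written as a
machine-readable JSON document plus a human-readable summary.  All dialects
round-trip exactly; logging never alters results.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .builders import DEFAULT_CONFIG, WatershedConfig
from .estimator import FitResult, SampleMoments
from .pipeline import BatteryReport, FitThresholds

__all__ = [
    "RunConfig",
    "read_covariance",
    "write_covariance",
    "read_raw_table",
    "write_report",
    "read_report",
]

logger = logging.getLogger("watershed_sem")

_CANONICAL = (
    list(DEFAULT_CONFIG.wm_tracts)
    + list(DEFAULT_CONFIG.ps_variables)
    + list(DEFAULT_CONFIG.fi_indicators)
)


@dataclass
class RunConfig:
    """Configuration for a battery run, loadable from YAML."""

    covariance_path: str | None = None
    raw_path: str | None = None
    n: int | None = None
    name_map: dict[str, str] = field(default_factory=dict)  # dataset name -> canonical
    fi_indicators: list[str] = field(default_factory=lambda: list(DEFAULT_CONFIG.fi_indicators))
    ps_variables: list[str] = field(default_factory=lambda: list(DEFAULT_CONFIG.ps_variables))
    wm_tracts: list[str] = field(default_factory=lambda: list(DEFAULT_CONFIG.wm_tracts))
    covariates: list[str] = field(default_factory=list)
    thresholds: FitThresholds = field(default_factory=FitThresholds)
    subset_contests: bool = True
    subset_k: int = 6
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        thresholds = FitThresholds(**payload.pop("thresholds", {}))
        return cls(thresholds=thresholds, **payload)

    def watershed_config(self) -> WatershedConfig:
        return WatershedConfig(
            fi_indicators=tuple(self.fi_indicators),
            ps_variables=tuple(self.ps_variables),
            wm_tracts=tuple(self.wm_tracts),
            covariates=tuple(self.covariates),
        )


# ---------------------------------------------------------------------------
# covariance and raw-data dialects
# ---------------------------------------------------------------------------


def read_covariance(
    path: str | Path,
    n: int | None = None,
    names: list[str] | None = None,
    tol: float = 1e-8,
) -> SampleMoments:
    """Read a covariance matrix with header row and index column of names.

    The matrix must be square and symmetric within ``tol`` (it is symmetrized
    and the event logged); ``n`` may instead come from a ``# N=...`` line.
    """
    path = Path(path)
    meta_n = None
    with open(path) as fh:
        head = fh.readline()
        if head.startswith("#"):
            m = re.search(r"N\s*=\s*(\d+)", head)
            if m:
                meta_n = int(m.group(1))
    frame = pd.read_csv(path, index_col=0, comment="#", float_precision="round_trip")
    if frame.shape[0] != frame.shape[1]:
        raise ValueError(f"covariance block is not square: {frame.shape}")
    if list(frame.index) != list(frame.columns):
        raise ValueError("row names and column names disagree")
    try:
        S = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in covariance matrix: {exc}") from exc
    asym = np.abs(S - S.T)
    if asym.max() > tol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"matrix asymmetric beyond tolerance at ({frame.index[i]}, {frame.columns[j]}): "
            f"{S[i, j]!r} vs {S[j, i]!r}"
        )
    if asym.max() > 0:
        logger.info("symmetrized covariance matrix (max asymmetry %.3g)", asym.max())
    S = 0.5 * (S + S.T)
    n_eff = n if n is not None else meta_n
    if n_eff is None:
        raise ValueError("sample size N must be given or present as a '# N=...' line")
    file_names = list(frame.columns)
    if names is not None:
        missing = [nm for nm in names if nm not in file_names]
        if missing:
            raise ValueError(f"expected variables absent from covariance file: {missing}")
    return SampleMoments(S=S, names=file_names, n=int(n_eff))


def write_covariance(moments: SampleMoments, path: str | Path) -> None:
    path = Path(path)
    frame = pd.DataFrame(moments.S, index=moments.names, columns=moments.names)
    with open(path, "w") as fh:
        fh.write(f"# N={moments.n}\n")
        frame.to_csv(fh, lineterminator="\n")


def read_raw_table(
    path: str | Path, name_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a subjects-by-variables table; complete-case enforcement (subjects
    with any missing value dropped, count logged); optional header renaming."""
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: table has no data rows")
    if name_map:
        frame = frame.rename(columns=name_map)
    n0 = len(frame)
    frame = frame.dropna(axis=0, how="any").reset_index(drop=True)
    dropped = n0 - len(frame)
    if dropped:
        logger.info("dropped %d incomplete subject(s) of %d", dropped, n0)
    frame.attrs["n_dropped"] = dropped
    logger.info("raw table: N=%d subjects, p=%d variables", len(frame), frame.shape[1])
    return frame


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    return x


def _fit_payload(fit: FitResult) -> dict:
    idx = fit.indices
    payload = {
        "T_ml": _round(fit.T_ml),
        "df": fit.df,
        "p_value": _round(fit.p_value),
        "aic": _round(fit.aic),
        "converged": fit.converged,
        "n_iterations": fit.n_iterations,
        "n_free": fit.n_free,
        "r2": {k: _round(v) for k, v in fit.r2.items()},
        "heywood": fit.heywood,
        "messages": fit.messages,
        "indices": None
        if idx is None
        else {
            "rmsea": _round(idx.rmsea, 3),
            "rmsea_ci_low": _round(idx.rmsea_ci_low, 3),
            "rmsea_ci_high": _round(idx.rmsea_ci_high, 3),
            "cfi": _round(idx.cfi, 3),
            "srmr": _round(idx.srmr, 3),
        },
        "parameters": [
            {
                "lhs": r.lhs,
                "op": r.op,
                "rhs": r.rhs,
                "free_index": r.free_index,
                "label": r.label,
                "estimate": _round(r.estimate),
                "se": _round(r.se),
            }
            for r in fit.table.rows
        ],
    }
    if fit.T_scaled is not None:
        payload["T_scaled"] = _round(fit.T_scaled)
        payload["scaling_factor"] = _round(fit.scaling_factor)
        payload["p_value_scaled"] = _round(fit.p_value_scaled)
    return payload


def report_payload(report: BatteryReport) -> dict:
    stages = {}
    for name, rec in report.stages.items():
        stages[name] = {
            "model_syntax": rec.model_syntax,
            "error": rec.error,
            "verdict": rec.verdict,
            "fit": None if rec.fit is None else _fit_payload(rec.fit),
        }
    comparisons = {
        name: {k: _round(v) for k, v in asdict(c).items()}
        for name, c in report.comparisons.items()
    }
    payload = {
        "config": {
            "fi_indicators": list(report.config.fi_indicators),
            "ps_variables": list(report.config.ps_variables),
            "wm_tracts": list(report.config.wm_tracts),
            "covariates": list(report.config.covariates),
        },
        "thresholds": asdict(report.thresholds),
        "stages": stages,
        "comparisons": comparisons,
        "modification_scan": [
            {"lhs": m.lhs, "op": m.op, "rhs": m.rhs, "mi": _round(m.mi, 3), "epc": _round(m.epc, 3)}
            for m in report.modification_scan[:20]
        ],
    }
    for key, frame in (
        ("subset_contests", report.subset_contests),
        ("subset_contests_covariate", report.subset_contests_covariate),
    ):
        if frame is not None:
            payload[key] = {
                "n_contests": int(len(frame)),
                "n_watershed_wins": int(frame["watershed_wins"].sum()),
                "delta_aic_min": _round(float(frame["delta_aic"].min()), 3),
                "delta_aic_max": _round(float(frame["delta_aic"].max()), 3),
                "contests": [
                    {k: _round(v, 3) if isinstance(v, float) else v for k, v in row.items()}
                    for row in frame.to_dict(orient="records")
                ],
            }
    return payload


def _summary_lines(payload: dict) -> list[str]:
    lines = ["Watershed battery summary", "=" * 25]
    for name, rec in payload["stages"].items():
        if rec["fit"] is None:
            lines.append(f"{name}: FAILED ({rec['error']})")
            continue
        f = rec["fit"]
        idx = f["indices"] or {}
        scaled = (
            f", T_scaled={f['T_scaled']:.3f} (c={f['scaling_factor']:.3f})"
            if "T_scaled" in f
            else ""
        )
        lines.append(
            f"{name}: T={f['T_ml']:.3f}, df={f['df']}, p={f['p_value']:.3f}{scaled}, "
            f"RMSEA={idx.get('rmsea')} [{idx.get('rmsea_ci_low')} {idx.get('rmsea_ci_high')}], "
            f"CFI={idx.get('cfi')}, SRMR={idx.get('srmr')}, AIC={f['aic']:.3f}"
        )
        lines.append(f"    verdicts: {rec['verdict']}")
    if payload["comparisons"]:
        lines.append("Comparisons:")
        for name, c in payload["comparisons"].items():
            lines.append(
                f"  {name}: dT={c['delta_T']:.3f}, ddf={c['delta_df']}, p={c['p_value']:.4g}, "
                f"dAIC={c['delta_aic']:.3f}, preferred={c['preferred']}"
            )
    for key in ("subset_contests", "subset_contests_covariate"):
        if key in payload:
            s = payload[key]
            lines.append(
                f"{key}: {s['n_watershed_wins']}/{s['n_contests']} watershed wins, "
                f"delta AIC range [{s['delta_aic_min']}, {s['delta_aic_max']}]"
            )
    return lines


def write_report(report: BatteryReport | dict, path: str | Path) -> None:
    """Write the machine-readable report (JSON) plus a ``.txt`` summary."""
    payload = report if isinstance(report, dict) else report_payload(report)
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=False)
        fh.write("\n")
    with open(path.with_suffix(".txt"), "w") as fh:
        fh.write("\n".join(_summary_lines(payload)) + "\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
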