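"""Builders for the watershed model battery.

Constructs every model in the staged analysis from a level-structured variable
configuration: the fluid-intelligence measurement model, the processing-speed
dimensionality models, the MIMIC model, the full three-level watershed model
(neural tracts -> processing speed -> latent fluid intelligence), its
constrained competitors, the inverted-hierarchy control, the covariate-adjusted
variant and the exhaustive tract-subset configurations.

Builders are pure: the same configuration always yields an identical
serialized model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

from .model import (
    COVARIANCE,
    LOADING,
    REGRESSION,
    ModelSpec,
    ParameterSpec,
    Variable,
)

__all__ = [
    "WatershedConfig",
    "DEFAULT_CONFIG",
    "VARIANT_KINDS",
    "build_measurement_model",
    "build_ps_factor_models",
    "build_mimic",
    "build_full_watershed",
    "build_inverted_watershed",
    "make_variant",
    "enumerate_tract_subsets",
]

# canonical variable names (JHU tract abbreviations; RT-derived speed and
# consistency scores; Cattell Culture Fair subtests)
_TRACTS = ["UNC", "SLF", "IFOF", "ATR", "FMin", "FMaj", "CST", "ILF", "CINGHipp", "CING"]
_PS = ["SRTspeed", "CRTspeed", "AVspeed", "SRTcons", "CRTcons", "AVcons"]
_CATTELL = ["Cattell1", "Cattell2", "Cattell3", "Cattell4"]


@dataclass(frozen=True)
class WatershedConfig:
    """Level-structured variable configuration for the watershed battery."""

    fi_indicators: tuple[str, ...] = tuple(_CATTELL)
    ps_variables: tuple[str, ...] = tuple(_PS)
    wm_tracts: tuple[str, ...] = tuple(_TRACTS)
    covariates: tuple[str, ...] = ()
    fi_name: str = "FI"
    # task/measure structure of the PS variables, derivable from the default
    # names; override for non-canonical naming
    ps_tasks: tuple[tuple[str, ...], ...] = (
        ("SRTspeed", "SRTcons"),
        ("CRTspeed", "CRTcons"),
        ("AVspeed", "AVcons"),
    )
    ps_measures: tuple[tuple[str, ...], ...] = (
        ("SRTspeed", "CRTspeed", "AVspeed"),
        ("SRTcons", "CRTcons", "AVcons"),
    )

    def __post_init__(self) -> None:
        groups = [self.fi_indicators, self.ps_variables, self.wm_tracts, self.covariates]
        seen: set[str] = set()
        for g in groups:
            for name in g:
                if name in seen:
                    raise ValueError(f"variable {name!r} appears in more than one level")
                seen.add(name)
        if self.fi_name in seen:
            raise ValueError(f"latent name {self.fi_name!r} collides with an observed variable")

    def observed_names(self) -> list[str]:
        return list(self.wm_tracts) + list(self.ps_variables) + list(self.fi_indicators) + list(
            self.covariates
        )

    def with_tracts(self, tracts: tuple[str, ...]) -> "WatershedConfig":
        return replace(self, wm_tracts=tuple(tracts))


DEFAULT_CONFIG = WatershedConfig()

VARIANT_KINDS = (
    "free",
    "zero_paths",
    "equal_paths",
    "strongest_only",
    "source_specific",
    "target_specific",
    "inverted",
    "plus_direct_path",
)


# ---------------------------------------------------------------------------
# level builders
# ---------------------------------------------------------------------------


def _cfa_parameters(factor: str, indicators: list[str]) -> list[ParameterSpec]:
    return [ParameterSpec(factor, LOADING, ind) for ind in indicators]


def build_measurement_model(indicators: list[str], factor: str = "FI") -> ModelSpec:
    """Single-factor CFA: one latent measured by all indicators (first loading
    fixed to 1 by the default identification convention)."""
    indicators = list(indicators)
    if len(indicators) < 3:
        raise ValueError("a single-factor model needs at least 3 indicators")
    variables = [Variable(n, "observed", "phenotype-indicator") for n in indicators]
    variables.append(Variable(factor, "latent"))
    return ModelSpec(variables=variables, parameters=_cfa_parameters(factor, indicators))


def build_ps_factor_models(config: WatershedConfig = DEFAULT_CONFIG) -> dict[str, ModelSpec]:
    """The three processing-speed dimensionality models.

    ``single``: one factor over the 6 PS measures; ``speed_consistency``: one
    factor per measure type with a factor covariance; ``task``: one factor per
    task (speed and consistency of the same task) with all factor covariances.
    """
    ps = list(config.ps_variables)
    for group in list(config.ps_tasks) + list(config.ps_measures):
        for name in group:
            if name not in ps:
                raise ValueError(f"task/measure assignment references unknown variable {name!r}")

    out: dict[str, ModelSpec] = {}
    out["single"] = build_measurement_model(ps, factor="PS")

    def multi(groups: list[tuple[str, ...]], prefix: str) -> ModelSpec:
        variables = [Variable(n, "observed", "endophenotype") for n in ps]
        params: list[ParameterSpec] = []
        factors = []
        for g, group in enumerate(groups, start=1):
            fac = f"{prefix}{g}"
            factors.append(fac)
            variables.append(Variable(fac, "latent"))
            params.extend(_cfa_parameters(fac, list(group)))
        for a, b in itertools.combinations(factors, 2):
            params.append(ParameterSpec(a, COVARIANCE, b))
        return ModelSpec(variables=variables, parameters=params)

    out["speed_consistency"] = multi(list(config.ps_measures), "PSmeas")
    out["task"] = multi(list(config.ps_tasks), "PStask")
    return out


def build_mimic(config: WatershedConfig = DEFAULT_CONFIG) -> ModelSpec:
    """MIMIC model: latent FI measured by the Cattell subtests and regressed on
    all six observed PS variables (which intercovary freely)."""
    ps = list(config.ps_variables)
    fi = list(config.fi_indicators)
    variables = (
        [Variable(n, "observed", "endophenotype") for n in ps]
        + [Variable(n, "observed", "phenotype-indicator") for n in fi]
        + [Variable(config.fi_name, "latent")]
    )
    params = _cfa_parameters(config.fi_name, fi)
    params += [ParameterSpec(config.fi_name, REGRESSION, x) for x in ps]
    # free intercovariances among the PS causes (explicit, for auditability)
    params += [ParameterSpec(a, COVARIANCE, b) for a, b in itertools.combinations(ps, 2)]
    return ModelSpec(variables=variables, parameters=params)


def build_full_watershed(config: WatershedConfig = DEFAULT_CONFIG) -> ModelSpec:
    """The full three-level watershed model.

    Every tract predicts every PS variable; every PS variable predicts latent
    FI; residual covariances are free within the tract level and within the PS
    level but no direct tract->FI, tract->indicator or PS->indicator paths
    exist (hierarchy violations would surface as misfit).  Optional binary
    health covariates predict every tract and intercovary freely.
    """
    wm = list(config.wm_tracts)
    ps = list(config.ps_variables)
    fi = list(config.fi_indicators)
    cov = list(config.covariates)
    variables = (
        [Variable(n, "observed", "neural") for n in wm]
        + [Variable(n, "observed", "endophenotype") for n in ps]
        + [Variable(n, "observed", "phenotype-indicator") for n in fi]
        + [Variable(n, "observed", "covariate") for n in cov]
        + [Variable(config.fi_name, "latent")]
    )
    params: list[ParameterSpec] = []
    params += [ParameterSpec(p, REGRESSION, t) for p in ps for t in wm]
    params += [ParameterSpec(config.fi_name, REGRESSION, p) for p in ps]
    params += _cfa_parameters(config.fi_name, fi)
    params += [ParameterSpec(a, COVARIANCE, b) for a, b in itertools.combinations(wm, 2)]
    params += [ParameterSpec(a, COVARIANCE, b) for a, b in itertools.combinations(ps, 2)]
    params += [ParameterSpec(t, REGRESSION, c) for t in wm for c in cov]
    params += [ParameterSpec(a, COVARIANCE, b) for a, b in itertools.combinations(cov, 2)]
    return ModelSpec(variables=variables, parameters=params)


def build_inverted_watershed(config: WatershedConfig = DEFAULT_CONFIG) -> ModelSpec:
    """Inverted-hierarchy control: the two lower levels are swapped, so PS
    predicts tract organisation which in turn predicts latent FI directly
    (PS variables intercovary freely; tract residuals covary freely)."""
    wm = list(config.wm_tracts)
    ps = list(config.ps_variables)
    fi = list(config.fi_indicators)
    cov = list(config.covariates)
    variables = (
        [Variable(n, "observed", "endophenotype") for n in ps]
        + [Variable(n, "observed", "neural") for n in wm]
        + [Variable(n, "observed", "phenotype-indicator") for n in fi]
        + [Variable(n, "observed", "covariate") for n in cov]
        + [Variable(config.fi_name, "latent")]
    )
    params: list[ParameterSpec] = []
    params += [ParameterSpec(t, REGRESSION, p) for t in wm for p in ps]
    params += [ParameterSpec(config.fi_name, REGRESSION, t) for t in wm]
    params += _cfa_parameters(config.fi_name, fi)
    params += [ParameterSpec(a, COVARIANCE, b) for a, b in itertools.combinations(ps, 2)]
    params += [ParameterSpec(a, COVARIANCE, b) for a, b in itertools.combinations(wm, 2)]
    params += [ParameterSpec(t, REGRESSION, c) for t in wm for c in cov]
    params += [ParameterSpec(a, COVARIANCE, b) for a, b in itertools.combinations(cov, 2)]
    return ModelSpec(variables=variables, parameters=params)


# ---------------------------------------------------------------------------
# constrained variants
# ---------------------------------------------------------------------------


def _path_block(
    spec: ModelSpec, config: WatershedConfig, block: str
) -> list[int]:
    """Indices of the regression rows forming the named path block."""
    if block == "wm_ps":
        lhs_set, rhs_set = set(config.ps_variables), set(config.wm_tracts)
    elif block == "ps_fi":
        lhs_set, rhs_set = {config.fi_name}, set(config.ps_variables)
    elif block == "wm_fi":  # inverted model's upper block
        lhs_set, rhs_set = {config.fi_name}, set(config.wm_tracts)
    else:
        raise ValueError(f"unknown path block {block!r}")
    idx = [
        i
        for i, p in enumerate(spec.parameters)
        if p.op == REGRESSION and p.lhs in lhs_set and p.rhs in rhs_set
    ]
    if not idx:
        raise ValueError(f"model has no {block!r} path block")
    return idx


def make_variant(
    base: ModelSpec,
    kind: str,
    *,
    config: WatershedConfig = DEFAULT_CONFIG,
    block: str = "wm_ps",
    source: str | None = None,
) -> ModelSpec:
    """Deterministic constrained transformation of a built model.

    ``zero_paths`` fixes the block to 0; ``equal_paths`` ties it under one
    label; ``strongest_only`` frees only the paths from ``source`` (an input,
    never auto-selected, so the battery is deterministic); ``source_specific``
    ties paths per source (equal across targets); ``target_specific`` ties
    per target (equal across sources); ``plus_direct_path`` adds a single
    ``source`` -> FI regression; ``inverted`` rebuilds the inverted hierarchy.

    Note: for the 10-tract, 6-measure block, ``source_specific`` imposes 50
    constraints (60 paths reduced to 10 tied values).
    """
    if kind == "free":
        return base.copy()
    if kind == "inverted":
        return build_inverted_watershed(config)

    spec = base.copy()
    if kind == "plus_direct_path":
        if source is None:
            raise ValueError("plus_direct_path requires a source variable name")
        if source not in spec.variable_names:
            raise ValueError(f"unknown source variable {source!r}")
        spec.parameters.append(ParameterSpec(config.fi_name, REGRESSION, source))
        return ModelSpec(variables=spec.variables, parameters=spec.parameters)

    idx = _path_block(spec, config, block)
    rows = [spec.parameters[i] for i in idx]
    if kind == "zero_paths":
        for r in rows:
            r.fixed, r.label = 0.0, None
    elif kind == "equal_paths":
        for r in rows:
            r.label = f"eq_{block}"
    elif kind == "strongest_only":
        if source is None:
            raise ValueError("strongest_only requires the source variable name")
        if source not in {r.rhs for r in rows}:
            raise ValueError(f"{source!r} is not a source in block {block!r}")
        for r in rows:
            if r.rhs != source:
                r.fixed, r.label = 0.0, None
    elif kind == "source_specific":
        for r in rows:
            r.label = f"src_{r.rhs}"
    elif kind == "target_specific":
        for r in rows:
            r.label = f"tgt_{r.lhs}"
    else:
        raise ValueError(f"unknown variant kind {kind!r}")
    return ModelSpec(variables=spec.variables, parameters=spec.parameters)


def enumerate_tract_subsets(
    tracts: list[str] | tuple[str, ...], k: int, config: WatershedConfig = DEFAULT_CONFIG
) -> list[WatershedConfig]:
    """All C(n, k) tract-subset configurations in lexicographic order of the
    input tract list (e.g. the 210 6-of-10 subsets of the contest battery)."""
    tracts = tuple(tracts)
    if not 0 < k <= len(tracts):
        raise ValueError(f"k={k} out of range for {len(tracts)} tracts")
    return [config.with_tracts(comb) for comb in itertools.combinations(tracts, k)]
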