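"""Symbolic covariance-structure models.

A model is a set of observed and latent variables plus a list of parameters
(loadings, regressions, covariances, variances), each free, fixed to a value,
or tied to other parameters through an equality label.  The plain-text syntax
mirrors the conventions of mainstream SEM software:

    FI =~ C1 + C2 + C3 + C4     # measurement: latent =~ indicators
    y ~ x1 + x2                 # regression
    a ~~ b                      # covariance
    a ~~ a                      # variance
    y ~ 0*x1 + b1*x2            # numeric premultiplier fixes, word labels tie
    y ~ start(0.3)*x3           # optional start value

Degrees of freedom are computed exactly as p(p+1)/2 minus the number of
distinct free parameters, p being the number of observed variables; means are
not modelled (covariance-only analysis of standardized variables).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx

__all__ = [
    "Variable",
    "ParameterSpec",
    "ModelSpec",
    "ParameterRow",
    "ParameterTable",
    "ModelSyntaxError",
    "ModelValidationError",
    "IdentificationError",
    "parse_model_syntax",
    "serialize_model_syntax",
    "build_parameter_table",
    "model_df",
]

LOADING = "loading"
REGRESSION = "regression"
COVARIANCE = "covariance"
VARIANCE = "variance"

_OPS = (LOADING, REGRESSION, COVARIANCE, VARIANCE)


class ModelSyntaxError(ValueError):
    """Raised when model-syntax text cannot be parsed."""


class ModelValidationError(ValueError):
    """Raised when a structurally invalid model is declared."""


class IdentificationError(ModelValidationError):
    """Raised on conflicting latent-scale identification constraints."""


@dataclass(frozen=True)
class Variable:
    """A named model variable, observed or latent, with an optional level tag."""

    name: str
    kind: str = "observed"  # "observed" | "latent"
    level: str | None = None  # e.g. "neural" | "endophenotype" | "phenotype-indicator"

    def __post_init__(self) -> None:
        if self.kind not in ("observed", "latent"):
            raise ModelValidationError(f"unknown variable kind {self.kind!r}")


@dataclass
class ParameterSpec:
    """One parameter: lhs op rhs, with free/fixed/labelled status.

    Orientation conventions: for a loading, ``lhs`` is the latent factor and
    ``rhs`` the indicator; for a regression, ``lhs`` is the dependent variable
    and ``rhs`` the predictor; covariances are unordered (canonicalized by
    variable declaration order); a variance has ``lhs == rhs``.
    """

    lhs: str
    op: str
    rhs: str
    fixed: float | None = None
    label: str | None = None
    start: float | None = None

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ModelValidationError(f"unknown parameter op {self.op!r}")
        if self.op == VARIANCE and self.lhs != self.rhs:
            raise ModelValidationError(
                f"variance parameter requires lhs == rhs, got {self.lhs!r} ~~ {self.rhs!r}"
            )
        if self.fixed is not None:
            if self.label is not None:
                raise ModelValidationError(
                    f"{self.key()}: parameter cannot be both fixed and labelled"
                )
            if not math.isfinite(self.fixed):
                raise ModelValidationError(f"{self.key()}: fixed value must be finite")

    @property
    def free(self) -> bool:
        return self.fixed is None

    def key(self) -> tuple[str, str, str]:
        return (self.lhs, self.op, self.rhs)


@dataclass
class ModelSpec:
    """A validated symbolic model: variables plus parameters."""

    variables: list[Variable]
    parameters: list[ParameterSpec]

    def __post_init__(self) -> None:
        self.validate()

    # -- convenience ------------------------------------------------------
    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def observed_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "observed"]

    @property
    def latent_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "latent"]

    def endogenous_names(self) -> list[str]:
        """Variables receiving at least one directed edge (loading target or
        regression outcome), in declaration order."""
        endo = set()
        for par in self.parameters:
            if par.op == LOADING:
                endo.add(par.rhs)
            elif par.op == REGRESSION:
                endo.add(par.lhs)
        return [n for n in self.variable_names if n in endo]

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        names = self.variable_names
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ModelValidationError(f"duplicate variable names: {dupes}")
        order = {n: i for i, n in enumerate(names)}

        seen: set[tuple[str, str, str]] = set()
        for par in self.parameters:
            for ref in (par.lhs, par.rhs):
                if ref not in order:
                    raise ModelValidationError(
                        f"parameter {par.key()} references undeclared variable {ref!r}"
                    )
            # canonicalize covariance orientation by declaration order
            if par.op == COVARIANCE and order[par.lhs] > order[par.rhs]:
                par.lhs, par.rhs = par.rhs, par.lhs
            if par.key() in seen:
                raise ModelValidationError(f"duplicate parameter {par.key()}")
            seen.add(par.key())

        # directed graph (loadings: factor -> indicator; regressions: predictor -> outcome)
        g = nx.DiGraph()
        g.add_nodes_from(names)
        for par in self.parameters:
            if par.op == LOADING:
                g.add_edge(par.lhs, par.rhs)
            elif par.op == REGRESSION:
                g.add_edge(par.rhs, par.lhs)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ModelValidationError(f"directed cycle among regressions: {cycle}")

        # every latent must do something
        touched = set()
        for par in self.parameters:
            if par.op in (LOADING, REGRESSION):
                touched.update((par.lhs, par.rhs))
        for lat in self.latent_names:
            if lat not in touched:
                raise ModelValidationError(
                    f"latent variable {lat!r} has no indicators and no regressions"
                )

    def to_syntax(self) -> str:
        return serialize_model_syntax(self)

    def copy(self) -> "ModelSpec":
        return ModelSpec(
            variables=list(self.variables),
            parameters=[replace(p) for p in self.parameters],
        )


# ---------------------------------------------------------------------------
# syntax parsing / serialization
# ---------------------------------------------------------------------------

_NAME_RE = r"[A-Za-z_][A-Za-z0-9_.]*"
_NUM_RE = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"
_TERM_RE = re.compile(
    rf"^(?:(?P<pre>{_NUM_RE}|start\(\s*(?P<sv>{_NUM_RE})\s*\)|{_NAME_RE})\*)?(?P<name>{_NAME_RE})$"
)


def _parse_term(term: str, lineno: int) -> tuple[str, float | None, str | None, float | None]:
    m = _TERM_RE.match(term.strip())
    if m is None:
        raise ModelSyntaxError(f"line {lineno}: cannot parse term {term!r}")
    name = m.group("name")
    pre = m.group("pre")
    fixed = label = start = None
    if pre is not None:
        if m.group("sv") is not None:
            start = float(m.group("sv"))
        else:
            try:
                fixed = float(pre)
            except ValueError:
                label = pre
    return name, fixed, label, start


def parse_model_syntax(text: str, levels: dict[str, str] | None = None) -> ModelSpec:
    """Parse plain-text model syntax into a validated :class:`ModelSpec`.

    Latent variables are inferred as the left-hand sides of ``=~`` statements;
    every other name is observed.  ``levels`` optionally tags variables.
    """
    params: list[ParameterSpec] = []
    latents: list[str] = []
    appearance: list[str] = []

    def note(name: str) -> None:
        if name not in appearance:
            appearance.append(name)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for token, op in (("=~", LOADING), ("~~", COVARIANCE), ("~", REGRESSION)):
            if token in line:
                lhs_s, rhs_s = line.split(token, 1)
                break
        else:
            raise ModelSyntaxError(f"line {lineno}: no operator in {line!r}")
        lhs = lhs_s.strip()
        if not re.fullmatch(_NAME_RE, lhs):
            raise ModelSyntaxError(f"line {lineno}: invalid left-hand side {lhs!r}")
        note(lhs)
        if op == LOADING and lhs not in latents:
            latents.append(lhs)
        for term in rhs_s.split("+"):
            name, fixed, label, start = _parse_term(term, lineno)
            this_op = op
            if op == COVARIANCE and name == lhs:
                this_op = VARIANCE
            note(name)
            par = ParameterSpec(lhs, this_op, name, fixed=fixed, label=label, start=start)
            if any(p.key() == par.key() for p in params):
                raise ModelSyntaxError(f"line {lineno}: duplicate parameter {par.key()}")
            params.append(par)

    variables = [
        Variable(
            n,
            kind="latent" if n in latents else "observed",
            level=(levels or {}).get(n),
        )
        for n in appearance
    ]
    return ModelSpec(variables=variables, parameters=params)


def _format_value(x: float) -> str:
    return repr(float(x)) if float(x) != int(x) else str(int(x))


def serialize_model_syntax(spec: ModelSpec) -> str:
    """Serialize one statement per parameter, byte-stable under round-trip."""
    op_token = {LOADING: "=~", REGRESSION: "~", COVARIANCE: "~~", VARIANCE: "~~"}
    lines = []
    for par in spec.parameters:
        pre = ""
        if par.fixed is not None:
            pre = f"{_format_value(par.fixed)}*"
        elif par.label is not None:
            pre = f"{par.label}*"
        elif par.start is not None:
            pre = f"start({_format_value(par.start)})*"
        lines.append(f"{par.lhs} {op_token[par.op]} {pre}{par.rhs}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# parameter table
# ---------------------------------------------------------------------------


@dataclass
class ParameterRow:
    lhs: str
    op: str
    rhs: str
    fixed: float | None = None
    label: str | None = None
    start: float | None = None
    free_index: int | None = None
    estimate: float | None = None
    se: float | None = None

    @property
    def free(self) -> bool:
        return self.fixed is None

    def key(self) -> tuple[str, str, str]:
        return (self.lhs, self.op, self.rhs)


@dataclass
class ParameterTable:
    """Flattened model: explicit plus implicit parameters with free indices.

    Equality-labelled rows share one free index; fixed rows carry none.
    """

    spec: ModelSpec
    rows: list[ParameterRow] = field(default_factory=list)

    @property
    def n_free(self) -> int:
        idx = {r.free_index for r in self.rows if r.free_index is not None}
        return len(idx)

    def free_row_keys(self) -> set[tuple[str, str, str]]:
        return {r.key() for r in self.rows if r.free}

    def values(self) -> dict[tuple[str, str, str], float]:
        out = {}
        for r in self.rows:
            out[r.key()] = r.fixed if r.fixed is not None else r.estimate
        return out

    def set_values(self, values: dict[tuple[str, str, str], float]) -> None:
        for r in self.rows:
            if r.key() in values:
                if r.free:
                    r.estimate = float(values[r.key()])
                else:
                    r.fixed = float(values[r.key()])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lhs": [r.lhs for r in self.rows],
                "op": [r.op for r in self.rows],
                "rhs": [r.rhs for r in self.rows],
                "free_index": [r.free_index for r in self.rows],
                "label": [r.label for r in self.rows],
                "fixed": [r.fixed for r in self.rows],
                "estimate": [r.estimate for r in self.rows],
                "se": [r.se for r in self.rows],
            }
        )


def build_parameter_table(spec: ModelSpec, check_identification: bool = True) -> ParameterTable:
    """Expand a :class:`ModelSpec` into a :class:`ParameterTable`.

    Adds the conventional implicit parameters: a (residual) variance for every
    variable lacking one, free covariances among exogenous observed regression
    predictors, and — for any latent factor lacking a scale constraint — a
    first loading fixed to 1.
    """
    rows = [
        ParameterRow(p.lhs, p.op, p.rhs, fixed=p.fixed, label=p.label, start=p.start)
        for p in spec.parameters
    ]
    keys = {r.key() for r in rows}
    order = {n: i for i, n in enumerate(spec.variable_names)}

    # latent scale identification
    for lat in spec.latent_names:
        loadings = [r for r in rows if r.op == LOADING and r.lhs == lat]
        has_fixed_loading = any(not r.free for r in loadings)
        var_rows = [r for r in rows if r.op == VARIANCE and r.lhs == lat]
        has_fixed_variance = any(not r.free for r in var_rows)
        if has_fixed_loading and has_fixed_variance and check_identification:
            raise IdentificationError(
                f"latent {lat!r}: both a loading and the factor variance are fixed"
            )
        if not has_fixed_loading and not has_fixed_variance:
            if loadings:
                loadings[0].fixed = 1.0
                loadings[0].label = None
            # a latent with no indicators (e.g. higher-order regressions only)
            # is left to explicit user constraints

    endo = set(spec.endogenous_names())

    # implicit (residual) variances for every variable missing one
    for name in spec.variable_names:
        if (name, VARIANCE, name) not in keys:
            rows.append(ParameterRow(name, VARIANCE, name))
            keys.add((name, VARIANCE, name))

    # implicit covariances among exogenous observed regression predictors
    predictors = []
    for p in spec.parameters:
        if p.op == REGRESSION and p.rhs not in endo:
            v = next(v for v in spec.variables if v.name == p.rhs)
            if v.kind == "observed" and p.rhs not in predictors:
                predictors.append(p.rhs)
    predictors.sort(key=order.__getitem__)
    for i, a in enumerate(predictors):
        for b in predictors[i + 1 :]:
            if (a, COVARIANCE, b) not in keys and (b, COVARIANCE, a) not in keys:
                rows.append(ParameterRow(a, COVARIANCE, b))
                keys.add((a, COVARIANCE, b))

    # free-index assignment with equality-label merging
    label_index: dict[str, int] = {}
    next_index = 0
    for r in rows:
        if not r.free:
            continue
        if r.label is not None:
            if r.label in label_index:
                r.free_index = label_index[r.label]
                continue
            label_index[r.label] = next_index
        r.free_index = next_index
        next_index += 1

    return ParameterTable(spec=spec, rows=rows)


def model_df(spec: ModelSpec, observed_count: int | None = None) -> int:
    """Degrees of freedom: non-redundant moments minus free parameters."""
    table = build_parameter_table(spec)
    p = observed_count if observed_count is not None else len(spec.observed_names)
    df = p * (p + 1) // 2 - table.n_free
    if df < 0:
        warnings.warn(
            f"model has negative degrees of freedom ({df}); it is not identified",
            stacklevel=2,
        )
    return df
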