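"""Maximum-likelihood covariance-structure estimation.

Implements the full inferential toolkit for the hierarchical MIMIC analysis:

* ML fitting of a symbolic model to a sample covariance matrix by
  quasi-Newton minimization of the normal-theory discrepancy
  ``F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p``, with T = (N-1) F.
* Standard errors from the inverse expected information; when raw data are
  available, Satorra-Bentler scaled test statistics and sandwich (robust)
  standard errors computed from fourth-order sample moments.
* RMSEA (with 90% CI by noncentral-chi-square inversion), CFI against the
  independence baseline, SRMR, AIC, squared multiple correlations, univariate
  modification indices, and nested chi-square difference tests.

The user-facing entry points are :func:`fit_model` and the scikit-learn style
:class:`StructuralEquationModel`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator

from ._ram import RAMSystem
from .model import (
    COVARIANCE,
    LOADING,
    REGRESSION,
    VARIANCE,
    ModelSpec,
    ParameterTable,
    build_parameter_table,
)

__all__ = [
    "SampleMoments",
    "FitIndices",
    "FitResult",
    "ComparisonResult",
    "ModificationIndex",
    "StructuralEquationModel",
    "implied_covariance",
    "ml_discrepancy",
    "fit_model",
    "fit_indices",
    "robust_statistics",
    "modification_indices",
    "compare_nested",
    "aic",
    "r_squared",
]


# ---------------------------------------------------------------------------
# sample moments
# ---------------------------------------------------------------------------


@dataclass
class SampleMoments:
    """Sample covariance matrix S with variable names, N, and optional raw data."""

    S: np.ndarray
    names: list[str]
    n: int
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2 or self.S.shape[0] != self.S.shape[1]:
            raise ValueError("S must be a square matrix")
        if len(self.names) != self.S.shape[0]:
            raise ValueError("names must match the dimension of S")
        if not np.allclose(self.S, self.S.T, atol=1e-8):
            raise ValueError("S must be symmetric")
        self.S = 0.5 * (self.S + self.S.T)
        if np.any(np.diag(self.S) < 0):
            raise ValueError("S has a negative diagonal entry")
        if self.raw is not None:
            self.raw = np.asarray(self.raw, dtype=float)
            if self.raw.shape != (self.n, len(self.names)):
                raise ValueError("raw data shape must be (n, p)")

    @classmethod
    def from_data(cls, X, names: list[str] | None = None) -> "SampleMoments":
        """Moments from an N x p table (DataFrame or array); S uses denominator N-1."""
        if isinstance(X, pd.DataFrame):
            names = list(X.columns) if names is None else names
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if names is None:
            names = [f"x{i + 1}" for i in range(X.shape[1])]
        S = np.cov(X, rowvar=False, ddof=1)
        return cls(S=np.atleast_2d(S), names=list(names), n=X.shape[0], raw=X)

    def select(self, names: list[str]) -> "SampleMoments":
        """Restrict to the named variables (pipeline selects modelled variables by name)."""
        pos = []
        for nm in names:
            if nm not in self.names:
                raise KeyError(f"variable {nm!r} not present in sample moments")
            pos.append(self.names.index(nm))
        pos = np.asarray(pos)
        raw = self.raw[:, pos] if self.raw is not None else None
        return SampleMoments(S=self.S[np.ix_(pos, pos)], names=list(names), n=self.n, raw=raw)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class FitIndices:
    rmsea: float
    rmsea_ci_low: float
    rmsea_ci_high: float
    cfi: float
    srmr: float


@dataclass
class FitResult:
    spec: ModelSpec
    table: ParameterTable
    theta: np.ndarray
    S: np.ndarray
    names: list[str]
    n: int
    F_min: float
    T_ml: float
    df: int
    p_value: float
    converged: bool
    n_iterations: int
    aic: float
    baseline_T: float | None = None
    baseline_df: int | None = None
    indices: FitIndices | None = None
    r2: dict[str, float] = field(default_factory=dict)
    se_expected: np.ndarray | None = None
    # robust quantities (present when raw data were supplied)
    scaling_factor: float | None = None
    T_scaled: float | None = None
    p_value_scaled: float | None = None
    se_robust: np.ndarray | None = None
    baseline_scaling: float | None = None
    indices_scaled: FitIndices | None = None
    heywood: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)
    _ram: RAMSystem | None = None

    @property
    def n_free(self) -> int:
        return self.table.n_free

    @property
    def implied(self) -> np.ndarray:
        return self._ram.implied_covariance(self.theta)

    def parameter_frame(self) -> pd.DataFrame:
        return self.table.to_frame()

    def summary(self) -> str:
        lines = [
            f"T_ml = {self.T_ml:.3f}, df = {self.df}, p = {self.p_value:.3f}, "
            f"AIC = {self.aic:.3f}, converged = {self.converged}",
        ]
        if self.T_scaled is not None:
            lines.append(
                f"T_scaled = {self.T_scaled:.3f} (scaling factor {self.scaling_factor:.3f})"
            )
        if self.indices is not None:
            i = self.indices
            lines.append(
                f"RMSEA = {i.rmsea:.3f} [{i.rmsea_ci_low:.3f} {i.rmsea_ci_high:.3f}], "
                f"CFI = {i.cfi:.3f}, SRMR = {i.srmr:.3f}"
            )
        return "\n".join(lines)


@dataclass
class ComparisonResult:
    delta_T: float
    delta_df: int
    p_value: float
    delta_aic: float
    preferred: str
    delta_T_scaled: float | None = None
    p_value_scaled: float | None = None
    restricted_id: str = "restricted"
    full_id: str = "full"


@dataclass
class ModificationIndex:
    lhs: str
    op: str
    rhs: str
    mi: float
    epc: float


# ---------------------------------------------------------------------------
# basic covariance-structure algebra
# ---------------------------------------------------------------------------


def implied_covariance(table: ParameterTable) -> np.ndarray:
    """Implied covariance over observed variables from a fully valued table."""
    ram = RAMSystem(table)
    theta = ram.theta_from_table() if ram.n_free else np.empty(0)
    sigma = ram.implied_covariance(theta)
    if not np.all(np.isfinite(sigma)):
        raise ValueError("implied covariance is not finite")
    return sigma


def _assert_pd(M: np.ndarray, name: str) -> None:
    try:
        linalg.cholesky(M, lower=True)
    except linalg.LinAlgError:
        raise ValueError(f"{name} is not positive definite") from None


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Normal-theory ML discrepancy F(S, Sigma); zero iff S == Sigma."""
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if S.shape != Sigma.shape:
        raise ValueError("S and Sigma must have the same order")
    _assert_pd(S, "S")
    _assert_pd(Sigma, "Sigma")
    p = S.shape[0]
    sign, logdet_Sigma = np.linalg.slogdet(Sigma)
    _, logdet_S = np.linalg.slogdet(S)
    return float(logdet_Sigma + np.trace(np.linalg.solve(Sigma, S)) - logdet_S - p)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _independence_fit(S: np.ndarray, n: int) -> tuple[float, int]:
    """Analytic fit of the independence baseline (free variances only)."""
    p = S.shape[0]
    _, logdet_S = np.linalg.slogdet(S)
    F = float(np.sum(np.log(np.diag(S))) - logdet_S)
    return (n - 1) * F, p * (p - 1) // 2


def _minimize(ram: RAMSystem, S: np.ndarray, gtol: float, max_iter: int):
    _, logdet_S = np.linalg.slogdet(S)
    x0 = ram.start_values(S)
    # guard: shrink covariance starts until the starting point is feasible
    for _ in range(40):
        F0, _, ok = ram.discrepancy_grad(x0, S, logdet_S)
        if ok:
            break
        off = ram.p_i != ram.p_j
        x0[ram.p_t[off]] *= 0.5
        x0[ram.b_t] *= 0.5

    def fun(x):
        F, g, _ = ram.discrepancy_grad(x, S, logdet_S)
        return F, g

    res = optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 10 * max_iter, "ftol": 1e-14, "gtol": gtol},
    )
    F, g, ok = ram.discrepancy_grad(res.x, S, logdet_S)
    if not (res.success and ok) or np.linalg.norm(g, ord=np.inf) > 100 * gtol:
        res2 = optimize.minimize(
            fun,
            res.x,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-16, "gtol": gtol / 10},
        )
        if res2.fun <= res.fun:
            res2.nit += res.nit
            res = res2
        F, g, ok = ram.discrepancy_grad(res.x, S, logdet_S)
    x = res.x
    n_iter = int(res.nit)
    # Fisher-scoring polish: cracks ill-conditioned valleys (near-singular S,
    # just-identified models) where quasi-Newton stalls
    for _ in range(30):
        if not ok or np.linalg.norm(g, ord=np.inf) <= gtol:
            break
        try:
            J = ram.sigma_jacobian(x)
            Sigma = ram.implied_covariance(x)
            iSig = np.linalg.inv(Sigma)
            AJ = np.einsum("ab,qbc->qac", iSig, J)
            H = np.einsum("qab,rba->qr", AJ, AJ)  # expected Hessian of F
            step = np.linalg.solve(H + 1e-12 * np.eye(H.shape[0]), -g)
        except np.linalg.LinAlgError:
            break
        improved = False
        for scale in (1.0, 0.5, 0.25, 0.1, 0.01):
            F_new, g_new, ok_new = ram.discrepancy_grad(x + scale * step, S, logdet_S)
            if ok_new and F_new <= F:
                x = x + scale * step
                F, g, ok = F_new, g_new, ok_new
                improved = True
                break
        n_iter += 1
        if not improved:
            break
    converged = bool(ok and np.linalg.norm(g, ord=np.inf) < max(1e-5, 100 * gtol))
    return x, max(F, 0.0), converged, n_iter


def _expected_information(ram: RAMSystem, theta: np.ndarray, Sigma: np.ndarray, n: int):
    J = ram.sigma_jacobian(theta)  # (q, p, p)
    iSig = np.linalg.inv(Sigma)
    AJ = np.einsum("ab,qbc->qac", iSig, J)
    info = 0.5 * (n - 1) * np.einsum("qab,rba->qr", AJ, AJ)
    return info, J, iSig


def fit_model(
    model: ModelSpec | ParameterTable | str,
    data: SampleMoments,
    *,
    robust: bool | None = None,
    compute_baseline: bool = True,
    compute_se: bool = True,
    max_iter: int = 2000,
    gtol: float = 1e-8,
    ridge: bool = False,
) -> FitResult:
    """Fit a model to sample moments by maximum likelihood.

    ``robust=None`` computes Satorra-Bentler statistics whenever raw data are
    attached to ``data``.  A non-positive-definite S is refused unless
    ``ridge=True``, which adds 1e-6 * mean(diag) to the diagonal (with a loud
    warning).
    """
    if isinstance(model, str):
        from .model import parse_model_syntax

        model = parse_model_syntax(model)
    table = model if isinstance(model, ParameterTable) else build_parameter_table(model)
    spec = table.spec

    moments = data if list(data.names) == spec.observed_names else data.select(spec.observed_names)
    S = moments.S.copy()
    p = S.shape[0]
    n = moments.n
    if n < p + 1:
        raise ValueError(f"sample size N={n} too small for p={p} observed variables")
    eigmin = float(np.min(np.linalg.eigvalsh(S)))
    if eigmin <= 0:
        if not ridge:
            raise ValueError(
                f"sample covariance is not positive definite (min eigenvalue {eigmin:.3e}); "
                "pass ridge=True to regularize"
            )
        bump = 1e-6 * float(np.mean(np.diag(S))) - eigmin
        warnings.warn(
            f"sample covariance not positive definite; adding ridge {bump:.3e} to the diagonal",
            stacklevel=2,
        )
        S = S + bump * np.eye(p)

    ram = RAMSystem(table)
    theta, F_min, converged, n_iter = _minimize(ram, S, gtol, max_iter)
    T_ml = (n - 1) * F_min
    df = p * (p + 1) // 2 - ram.n_free
    p_value = float(stats.chi2.sf(T_ml, df)) if df > 0 else float("nan")
    Sigma = ram.implied_covariance(theta)

    # write estimates back into the table
    for row in table.rows:
        if row.free:
            row.estimate = float(theta[row.free_index])
        else:
            row.estimate = row.fixed

    heywood = [
        r.lhs for r in table.rows if r.op == VARIANCE and r.estimate is not None and r.estimate < 0
    ]

    result = FitResult(
        spec=spec,
        table=table,
        theta=theta,
        S=S,
        names=list(moments.names),
        n=n,
        F_min=F_min,
        T_ml=T_ml,
        df=df,
        p_value=p_value,
        converged=converged,
        n_iterations=n_iter,
        aic=T_ml + 2 * ram.n_free,
        heywood=heywood,
        _ram=ram,
    )
    if not converged:
        result.messages.append("optimizer did not meet the convergence criterion")
    if heywood:
        result.messages.append(f"negative residual variance (Heywood case) for: {heywood}")

    if compute_se and ram.n_free:
        info, J, iSig = _expected_information(ram, theta, Sigma, n)
        try:
            acov = linalg.inv(info)
        except linalg.LinAlgError:
            acov = linalg.pinv(info)
            result.messages.append("expected information singular; pseudo-inverse used")
        se = np.sqrt(np.clip(np.diag(acov), 0.0, None))
        result.se_expected = se
        for row in table.rows:
            row.se = float(se[row.free_index]) if row.free else None

    if compute_baseline:
        result.baseline_T, result.baseline_df = _independence_fit(S, n)
        result.indices = fit_indices(
            T_ml, df, n, result.baseline_T, result.baseline_df, S=S, Sigma=Sigma
        )

    result.r2 = r_squared(result)

    if robust is None:
        robust = moments.raw is not None
    if robust:
        if moments.raw is None:
            raise ValueError("robust statistics require raw data in SampleMoments")
        robust_statistics(result, moments.raw)

    return result


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------


def _rmsea_ci(T: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """90% RMSEA interval by inverting the noncentral chi-square CDF."""
    lo_q, hi_q = (1 + level) / 2.0, (1 - level) / 2.0  # 0.95, 0.05

    def solve(target: float) -> float:
        # find nc >= 0 with ncx2.cdf(T, df, nc) == target (cdf decreasing in nc)
        if stats.chi2.cdf(T, df) < target:
            return 0.0
        hi = max(10.0, 2 * T)
        while stats.ncx2.cdf(T, df, hi) > target and hi < 1e7:
            hi *= 2
        return float(optimize.brentq(lambda nc: stats.ncx2.cdf(T, df, nc) - target, 0, hi))

    nc_low = solve(lo_q)
    nc_high = solve(hi_q)
    denom = df * (n - 1)
    return float(np.sqrt(nc_low / denom)), float(np.sqrt(nc_high / denom))


def fit_indices(
    T: float,
    df: int,
    n: int,
    T_base: float,
    df_base: int,
    S: np.ndarray | None = None,
    Sigma: np.ndarray | None = None,
) -> FitIndices:
    """RMSEA (+90% CI), CFI versus the independence baseline, and SRMR."""
    if df > 0:
        rmsea = float(np.sqrt(max(T - df, 0.0) / (df * (n - 1))))
        ci_low, ci_high = _rmsea_ci(T, df, n)
    else:
        rmsea = ci_low = ci_high = float("nan")
    denom = max(T - df, T_base - df_base, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(T - df, 0.0) / denom
    srmr = float("nan")
    if S is not None and Sigma is not None:
        d = np.sqrt(np.diag(S))
        resid = (S - Sigma) / np.outer(d, d)
        tri = np.tril_indices(S.shape[0])
        srmr = float(np.sqrt(np.mean(resid[tri] ** 2)))
    return FitIndices(
        rmsea=rmsea, rmsea_ci_low=ci_low, rmsea_ci_high=ci_high, cfi=float(cfi), srmr=srmr
    )


# ---------------------------------------------------------------------------
# Satorra-Bentler robust statistics
# ---------------------------------------------------------------------------


def _duplication(p: int) -> np.ndarray:
    ps = p * (p + 1) // 2
    D = np.zeros((p * p, ps))
    ti, tj = np.tril_indices(p)
    for col, (i, j) in enumerate(zip(ti, tj)):
        D[i + j * p, col] = 1.0
        D[j + i * p, col] = 1.0
    return D


def _gamma_adf(raw: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of sqrt(N) vech(S) from fourth-order moments."""
    xc = raw - raw.mean(axis=0)
    p = raw.shape[1]
    ti, tj = np.tril_indices(p)
    W = xc[:, ti] * xc[:, tj]
    return np.cov(W, rowvar=False, ddof=1)


def robust_statistics(fit: FitResult, raw: np.ndarray) -> FitResult:
    """Augment a fit with the Satorra-Bentler scaled statistic and sandwich SEs.

    The scaling factor is c = tr(U Gamma) / df with U the normal-theory
    residual weight matrix; T_scaled = T_ml / c.  Degrees of freedom are
    unchanged.  The scaled CFI uses scaled statistics of both the target and
    the independence baseline model.
    """
    raw = np.asarray(raw, dtype=float)
    p = len(fit.names)
    n = fit.n
    if raw.shape != (n, p):
        raise ValueError("raw data must be N x p matching the fitted moments")
    if n < p * (p + 1) // 2:
        warnings.warn(
            "N is small relative to the number of fourth-order moments; "
            "Satorra-Bentler quantities may be unstable",
            stacklevel=2,
        )
    ram = fit._ram
    Sigma = ram.implied_covariance(fit.theta)
    iSig = np.linalg.inv(Sigma)
    D = _duplication(p)
    V = 0.5 * D.T @ np.kron(iSig, iSig) @ D
    Gamma = _gamma_adf(raw)
    ti, tj = np.tril_indices(p)

    if ram.n_free:
        J = ram.sigma_jacobian(fit.theta)
        Delta = J[:, ti, tj].T  # (p*, q)
        VD = V @ Delta
        E = Delta.T @ VD
        try:
            Einv = linalg.inv(E)
        except linalg.LinAlgError:
            Einv = linalg.pinv(E)
        U = V - VD @ Einv @ VD.T
        bread = Einv @ (Delta.T @ V @ Gamma @ V @ Delta) @ Einv
        se_rob = np.sqrt(np.clip(np.diag(bread), 0.0, None) / (n - 1))
        fit.se_robust = se_rob
        for row in fit.table.rows:
            row.se = float(se_rob[row.free_index]) if row.free else None
    else:
        U = V

    if fit.df > 0:
        c = float(np.trace(U @ Gamma) / fit.df)
        if c <= 0:
            fit.messages.append("non-positive Satorra-Bentler scaling factor; left unscaled")
            c = 1.0
        fit.scaling_factor = c
        fit.T_scaled = fit.T_ml / c
        fit.p_value_scaled = float(stats.chi2.sf(fit.T_scaled, fit.df))
    else:
        fit.scaling_factor = 1.0
        fit.T_scaled = fit.T_ml
        fit.p_value_scaled = fit.p_value

    # scaled baseline and scaled indices
    if fit.baseline_T is not None and fit.baseline_df:
        Sigma_b = np.diag(np.diag(fit.S))
        iSig_b = np.linalg.inv(Sigma_b)
        Vb = 0.5 * D.T @ np.kron(iSig_b, iSig_b) @ D
        diag_cols = np.flatnonzero(ti == tj)
        Db = np.zeros((p * (p + 1) // 2, p))
        Db[diag_cols, np.arange(p)] = 1.0
        VDb = Vb @ Db
        Ub = Vb - VDb @ linalg.inv(Db.T @ VDb) @ VDb.T
        cb = float(np.trace(Ub @ Gamma) / fit.baseline_df)
        fit.baseline_scaling = cb
        fit.indices_scaled = fit_indices(
            fit.T_scaled,
            fit.df,
            n,
            fit.baseline_T / cb,
            fit.baseline_df,
            S=fit.S,
            Sigma=Sigma,
        )
    return fit


# ---------------------------------------------------------------------------
# modification indices
# ---------------------------------------------------------------------------


def _default_candidates(fit: FitResult) -> list[tuple[str, str, str]]:
    """All fixed-at-zero loadings, regressions and covariances (explicit rows
    fixed at zero plus structurally absent entries that keep the graph acyclic)."""
    import networkx as nx

    spec = fit.spec
    table = fit.table
    names = spec.variable_names
    latents = set(spec.latent_names)
    present = {r.key() for r in table.rows}
    free = {r.key() for r in table.rows if r.free}

    g = nx.DiGraph()
    g.add_nodes_from(names)
    for r in table.rows:
        if r.op == LOADING:
            g.add_edge(r.lhs, r.rhs)
        elif r.op == REGRESSION:
            g.add_edge(r.rhs, r.lhs)

    cands: list[tuple[str, str, str]] = []

    def consider(key: tuple[str, str, str]) -> bool:
        if key in free:
            return False
        for r in table.rows:
            if r.key() == key:
                return r.fixed == 0.0  # only fixed-at-zero rows are candidates
        return True

    for lat in sorted(latents, key=names.index):
        for obs in names:
            if obs in latents or obs == lat:
                continue
            key = (lat, LOADING, obs)
            if consider(key) and not nx.has_path(g, obs, lat):
                cands.append(key)
    for dep in names:
        for pred in names:
            if dep == pred:
                continue
            key = (dep, REGRESSION, pred)
            if (dep, LOADING, pred) in present or (pred, LOADING, dep) in present:
                continue
            if consider(key) and not nx.has_path(g, dep, pred):
                cands.append(key)
    order = {n: i for i, n in enumerate(names)}
    for a in names:
        for b in names:
            if order[a] >= order[b]:
                continue
            key = (a, COVARIANCE, b)
            if key in present and key not in free:
                if consider(key):
                    cands.append(key)
            elif key not in present:
                cands.append(key)
    return cands


def modification_indices(
    fit: FitResult,
    data: SampleMoments | None = None,
    candidates: list[tuple[str, str, str]] | None = None,
) -> list[ModificationIndex]:
    """Univariate score (Lagrange multiplier) statistics for fixed parameters.

    Each candidate gets the expected chi-square drop (1 df) from freeing it,
    with the expected parameter change; sorted by MI descending, ties broken
    by candidate enumeration order.  Candidates with numerically singular
    information are skipped.
    """
    if not fit.converged:
        warnings.warn("modification indices computed on a non-converged fit", stacklevel=2)
    ram = fit._ram
    n = fit.n
    S = fit.S
    Sigma = ram.implied_covariance(fit.theta)
    iSig = np.linalg.inv(Sigma)
    G = iSig - iSig @ S @ iSig

    if candidates is None:
        candidates = _default_candidates(fit)
    if not candidates:
        return []
    entries = [ram.entry_for(*key) for key in candidates]
    Jc = ram.candidate_jacobian(fit.theta, entries)  # (m, p, p)
    AJc = np.einsum("ab,qbc->qac", iSig, Jc)

    if ram.n_free:
        info, J, _ = _expected_information(ram, fit.theta, Sigma, n)
        AJ = np.einsum("ab,qbc->qac", iSig, J)
        I_ct = 0.5 * (n - 1) * np.einsum("cab,qba->cq", AJc, AJ)
        try:
            sol = np.linalg.solve(info, I_ct.T)  # (q, m)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(info, I_ct.T, rcond=None)[0]
        correction = np.einsum("cq,qc->c", I_ct, sol)
    else:
        correction = np.zeros(len(candidates))

    I_cc = 0.5 * (n - 1) * np.einsum("cab,cba->c", AJc, AJc)
    g_c = -0.5 * (n - 1) * np.einsum("ab,cba->c", G, Jc)
    denom = I_cc - correction

    out: list[ModificationIndex] = []
    scale = max(float(np.max(I_cc)), 1.0)
    for key, g, d in zip(candidates, g_c, denom):
        if d <= 1e-8 * scale:
            continue  # singular information for this candidate
        out.append(ModificationIndex(key[0], key[1], key[2], mi=float(g * g / d), epc=float(g / d)))
    out.sort(key=lambda m: -m.mi)
    return out


# ---------------------------------------------------------------------------
# model comparison and summaries
# ---------------------------------------------------------------------------


def _is_nested(restricted: FitResult, full: FitResult) -> bool:
    if restricted.names != full.names or restricted.n != full.n:
        return False
    if restricted.df < full.df:
        return False
    return restricted.table.free_row_keys() <= full.table.free_row_keys()


def compare_nested(
    restricted: FitResult,
    full: FitResult,
    restricted_id: str = "restricted",
    full_id: str = "full",
) -> ComparisonResult:
    """Chi-square difference test between nested fits (with the Satorra-Bentler
    scaled difference when both fits carry scaling factors)."""
    if not _is_nested(restricted, full):
        raise ValueError("models are not nested (or were fit to different data)")
    delta_T = restricted.T_ml - full.T_ml
    delta_df = restricted.df - full.df
    p = float(stats.chi2.sf(max(delta_T, 0.0), delta_df)) if delta_df > 0 else float("nan")
    delta_aic = restricted.aic - full.aic
    delta_T_scaled = p_scaled = None
    if restricted.scaling_factor is not None and full.scaling_factor is not None and delta_df > 0:
        c_d = (
            restricted.df * restricted.scaling_factor - full.df * full.scaling_factor
        ) / delta_df
        if c_d > 0:
            delta_T_scaled = delta_T / c_d
            p_scaled = float(stats.chi2.sf(max(delta_T_scaled, 0.0), delta_df))
    if delta_df > 0:
        preferred = full_id if (p < 0.05 if np.isfinite(p) else True) else restricted_id
    else:
        preferred = restricted_id if delta_aic <= 0 else full_id
    return ComparisonResult(
        delta_T=float(delta_T),
        delta_df=int(delta_df),
        p_value=p,
        delta_aic=float(delta_aic),
        preferred=preferred,
        delta_T_scaled=delta_T_scaled,
        p_value_scaled=p_scaled,
        restricted_id=restricted_id,
        full_id=full_id,
    )


def aic(fit: FitResult) -> float:
    """AIC on the discrepancy scale: T_ml + 2 q.  Differences between models on
    the same data equal differences of the full-likelihood AIC."""
    return fit.T_ml + 2 * fit.n_free


def r_squared(fit: FitResult) -> dict[str, float]:
    """Squared multiple correlation per endogenous variable:
    1 - residual variance / implied total variance (clipped into [0, 1])."""
    ram = fit._ram
    C = ram.implied_all(fit.theta)
    values = fit.table.values()
    out: dict[str, float] = {}
    for name in fit.spec.endogenous_names():
        i = ram.names.index(name)
        resid = values.get((name, VARIANCE, name))
        total = C[i, i]
        if resid is None or total <= 0:
            continue
        r2 = 1.0 - resid / total
        if r2 < 0 or r2 > 1:
            fit.messages.append(f"R-squared for {name} clipped from {r2:.3f} into [0, 1]")
            r2 = min(max(r2, 0.0), 1.0)
        out[name] = float(r2)
    return out


# ---------------------------------------------------------------------------
# scikit-learn style estimator
# ---------------------------------------------------------------------------


class StructuralEquationModel(BaseEstimator):
    """Structural equation model estimator with a scikit-learn interface.

    Fits a symbolic covariance-structure model (given as model-syntax text or
    a :class:`~watershed_sem.model.ModelSpec`) to raw data by maximum
    likelihood, exposing the fitted parameter table, test statistics, fit
    indices and per-equation R-squared as trailing-underscore attributes.

    Parameters
    ----------
    model : str or ModelSpec
        The model, in the plain-text syntax of :mod:`watershed_sem.model`.
    robust : bool, default True
        Compute Satorra-Bentler scaled statistics and sandwich standard
        errors from fourth-order moments when fitting raw data.
    ridge : bool, default False
        Regularize a non-positive-definite sample covariance.

    Examples
    --------
    >>> sem = StructuralEquationModel("FI =~ C1 + C2 + C3 + C4")
    >>> sem.fit(frame)                                    # doctest: +SKIP
    >>> sem.stat_, sem.df_                                # doctest: +SKIP
    """

    def __init__(
        self,
        model: str | ModelSpec = "",
        *,
        robust: bool = True,
        compute_baseline: bool = True,
        max_iter: int = 2000,
        gtol: float = 1e-8,
        ridge: bool = False,
    ):
        self.model = model
        self.robust = robust
        self.compute_baseline = compute_baseline
        self.max_iter = max_iter
        self.gtol = gtol
        self.ridge = ridge

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y=None):
        """Fit to an N x p data table (DataFrame with named columns, or array
        whose columns follow the model's observed-variable order)."""
        spec = self._spec()
        if isinstance(X, pd.DataFrame):
            moments = SampleMoments.from_data(X)
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        else:
            X = np.asarray(X, dtype=float)
            moments = SampleMoments.from_data(X, names=spec.observed_names)
        self.n_features_in_ = moments.S.shape[0]
        return self._finish(spec, moments, robust=self.robust)

    def fit_moments(self, S, n_obs: int, names: list[str] | None = None):
        """Fit directly to a sample covariance matrix (no robust statistics)."""
        spec = self._spec()
        if isinstance(S, pd.DataFrame):
            names = list(S.columns) if names is None else names
            S = S.to_numpy(dtype=float)
        if names is None:
            names = spec.observed_names
        moments = SampleMoments(S=np.asarray(S, dtype=float), names=list(names), n=int(n_obs))
        self.n_features_in_ = len(spec.observed_names)
        return self._finish(spec, moments, robust=False)

    def _spec(self) -> ModelSpec:
        if isinstance(self.model, ModelSpec):
            return self.model.copy()
        if isinstance(self.model, str) and self.model.strip():
            from .model import parse_model_syntax

            return parse_model_syntax(self.model)
        raise ValueError("model must be non-empty model-syntax text or a ModelSpec")

    def _finish(self, spec: ModelSpec, moments: SampleMoments, robust: bool):
        result = fit_model(
            spec,
            moments,
            robust=robust and moments.raw is not None,
            compute_baseline=self.compute_baseline,
            max_iter=self.max_iter,
            gtol=self.gtol,
            ridge=self.ridge,
        )
        self.result_ = result
        self.parameter_table_ = result.parameter_frame()
        self.estimates_ = result.theta.copy()
        self.se_ = (
            result.se_robust if result.se_robust is not None else result.se_expected
        )
        self.stat_ = result.T_ml
        self.stat_scaled_ = result.T_scaled
        self.scaling_factor_ = result.scaling_factor
        self.df_ = result.df
        self.p_value_ = result.p_value
        self.aic_ = result.aic
        self.r2_ = dict(result.r2)
        self.indices_ = result.indices
        self.rmsea_ = result.indices.rmsea if result.indices else float("nan")
        self.cfi_ = result.indices.cfi if result.indices else float("nan")
        self.srmr_ = result.indices.srmr if result.indices else float("nan")
        self.converged_ = result.converged
        self.n_iter_ = result.n_iterations
        self.implied_covariance_ = result.implied
        return self

    # -- scoring ----------------------------------------------------------
    def score(self, X, y=None) -> float:
        """Mean Gaussian log-likelihood of (centered) samples under the
        fitted implied covariance."""
        from scipy.stats import multivariate_normal

        if isinstance(X, pd.DataFrame):
            X = X[self.result_.names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float) - np.asarray(X, dtype=float).mean(axis=0)
        return float(
            np.mean(multivariate_normal.logpdf(X, cov=self.implied_covariance_))
        )
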