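"""Independent oracles used by the test suite.

These deliberately avoid the package's numerical machinery: the implied
covariance is built from the Neumann series of total effects (path-tracing)
instead of a matrix inverse, and the reference fit maximizes the raw
multivariate-normal log-likelihood with a derivative-free simplex search.
"""

import numpy as np
from scipy import optimize

from watershed_sem.model import (
    LOADING,
    REGRESSION,
    VARIANCE,
    build_parameter_table,
)


def path_tracing_sigma(table, values):
    """Implied covariance via the total-effects series sum_k B^k (acyclic B)."""
    spec = table.spec
    names = spec.observed_names + spec.latent_names
    k = len(names)
    idx = {n: i for i, n in enumerate(names)}
    B = np.zeros((k, k))
    Psi = np.zeros((k, k))
    for row in table.rows:
        v = values[row.key()]
        if row.op == LOADING:
            B[idx[row.rhs], idx[row.lhs]] = v
        elif row.op == REGRESSION:
            B[idx[row.lhs], idx[row.rhs]] = v
        else:
            Psi[idx[row.lhs], idx[row.rhs]] = Psi[idx[row.rhs], idx[row.lhs]] = v
    total = np.eye(k)
    power = np.eye(k)
    for _ in range(k):  # nilpotent for acyclic graphs
        power = power @ B
        if not power.any():
            break
        total = total + power
    C = total @ Psi @ total.T
    p = len(spec.observed_names)
    return C[:p, :p]


def simplex_ml_fit(spec, S, n, x0=None, maxiter=20000):
    """Reference ML estimates by Nelder-Mead on the Wishart log-likelihood.

    Returns (theta, F_min) on the same free-parameter indexing as the
    package's parameter table, but sharing none of its fitting code.
    """
    table = build_parameter_table(spec)
    q = table.n_free
    keys = {}
    for row in table.rows:
        if row.free:
            keys.setdefault(row.free_index, []).append(row.key())
    fixed = {row.key(): row.fixed for row in table.rows if not row.free}
    p = S.shape[0]
    sign, logdet_S = np.linalg.slogdet(S)

    def discrepancy(theta):
        values = dict(fixed)
        for j, ks in keys.items():
            for key in ks:
                values[key] = theta[j]
        sigma = path_tracing_sigma(table, values)
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e6
        logdet = 2 * np.sum(np.log(np.diag(L)))
        inv = np.linalg.inv(sigma)
        return logdet + np.sum(inv * S) - logdet_S - p

    if x0 is None:
        x0 = np.full(q, 0.4)
        for row in table.rows:
            if row.free and row.op == VARIANCE:
                x0[row.free_index] = 0.8
    res = optimize.minimize(
        discrepancy,
        x0,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-10, "fatol": 1e-12},
    )
    # polish with a second pass (simplex restarts help on flat valleys)
    res = optimize.minimize(
        discrepancy,
        res.x,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-12, "fatol": 1e-14},
    )
    return res.x, res.fun
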