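"""Reticular (RAM) parameterization of a covariance-structure model.

All variables (observed first, then latent) enter one directed-coefficient
matrix B (loadings and regressions) and one symmetric matrix Psi of
(residual) variances and covariances.  With A = (I - B)^-1 the implied
covariance of the observed block is

    Sigma(theta) = [A Psi A^T] restricted to observed rows/columns.

The class compiles a ParameterTable into index arrays so that assembling
Sigma, its analytic gradient, and the Jacobian d vech(Sigma)/d theta are all
plain vectorized numpy operations — the fit loop never touches Python-level
per-parameter dispatch.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .model import LOADING, REGRESSION, ParameterTable


class SingularStructuralMatrix(RuntimeError):
    """(I - B) is numerically singular for the supplied parameter values."""


class RAMSystem:
    def __init__(self, table: ParameterTable):
        spec = table.spec
        self.table = table
        self.obs_names = spec.observed_names
        self.names = self.obs_names + spec.latent_names
        self.p = len(self.obs_names)
        self.k = len(self.names)
        idx = {n: i for i, n in enumerate(self.names)}
        self.n_free = table.n_free

        self.B0 = np.zeros((self.k, self.k))
        self.Psi0 = np.zeros((self.k, self.k))

        b_i, b_j, b_t = [], [], []  # free B entries
        p_i, p_j, p_t = [], [], []  # free Psi entries (one per unordered pair)
        self._row_entry: list[tuple[str, int, int]] = []  # per table row, for values

        for row in table.rows:
            if row.op == LOADING:
                which, i, j = "B", idx[row.rhs], idx[row.lhs]
            elif row.op == REGRESSION:
                which, i, j = "B", idx[row.lhs], idx[row.rhs]
            else:  # variance / covariance
                which, i, j = "P", idx[row.lhs], idx[row.rhs]
            self._row_entry.append((which, i, j))
            if row.free:
                if which == "B":
                    b_i.append(i), b_j.append(j), b_t.append(row.free_index)
                else:
                    p_i.append(i), p_j.append(j), p_t.append(row.free_index)
            else:
                if which == "B":
                    self.B0[i, j] = row.fixed
                else:
                    self.Psi0[i, j] = self.Psi0[j, i] = row.fixed

        self.b_i = np.asarray(b_i, dtype=int)
        self.b_j = np.asarray(b_j, dtype=int)
        self.b_t = np.asarray(b_t, dtype=int)
        self.p_i = np.asarray(p_i, dtype=int)
        self.p_j = np.asarray(p_j, dtype=int)
        self.p_t = np.asarray(p_t, dtype=int)

    # -- parameter vector <-> matrices -----------------------------------
    def assemble(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        B = self.B0.copy()
        Psi = self.Psi0.copy()
        B[self.b_i, self.b_j] = theta[self.b_t]
        Psi[self.p_i, self.p_j] = theta[self.p_t]
        Psi[self.p_j, self.p_i] = theta[self.p_t]
        return B, Psi

    def start_values(self, S: np.ndarray | None = None) -> np.ndarray:
        """Default starts: 0.5 for loadings/paths, half the observed (co)variance
        for the Psi block, 0.5 for latent variances; explicit starts override.

        The Psi start is half of each observed sub-block of S, which keeps the
        starting implied covariance positive definite whenever S is.
        """
        theta = np.zeros(self.n_free)
        theta[self.b_t] = 0.5
        for i, j, t in zip(self.p_i, self.p_j, self.p_t):
            if i < self.p and j < self.p:
                theta[t] = 0.5 * (S[i, j] if S is not None else float(i == j))
            elif i == j:
                theta[t] = 0.5
            else:
                theta[t] = 0.0
        for row, (which, i, j) in zip(self.table.rows, self._row_entry):
            if row.free and row.start is not None:
                theta[row.free_index] = row.start
        return theta

    def theta_from_table(self) -> np.ndarray:
        """Read a full parameter vector from table estimates (truth tables)."""
        theta = np.full(self.n_free, np.nan)
        for row in self.table.rows:
            if row.free:
                if row.estimate is None:
                    raise ValueError(f"row {row.key()} has no value")
                theta[row.free_index] = row.estimate
        return theta

    def structural_inverse(self, B: np.ndarray) -> np.ndarray:
        ImB = np.eye(self.k) - B
        try:
            return linalg.solve(ImB, np.eye(self.k))
        except linalg.LinAlgError as exc:  # pragma: no cover - pathological input
            raise SingularStructuralMatrix(str(exc)) from exc

    def implied_all(self, theta: np.ndarray) -> np.ndarray:
        """Implied covariance over all variables (observed and latent)."""
        B, Psi = self.assemble(theta)
        A = self.structural_inverse(B)
        return A @ Psi @ A.T

    def implied_covariance(self, theta: np.ndarray) -> np.ndarray:
        return self.implied_all(theta)[: self.p, : self.p]

    # -- ML discrepancy and gradient --------------------------------------
    def discrepancy_grad(
        self, theta: np.ndarray, S: np.ndarray, logdet_S: float
    ) -> tuple[float, np.ndarray, bool]:
        """F_ML and its gradient; feasible=False when Sigma is not PD
        (a large penalty value is returned so line searches back off)."""
        p = self.p
        B, Psi = self.assemble(theta)
        A = self.structural_inverse(B)
        M = A @ Psi @ A.T
        Sigma = M[:p, :p]
        try:
            c, low = linalg.cho_factor(Sigma, check_finite=False)
        except (linalg.LinAlgError, ValueError):
            return 1e12, np.zeros(self.n_free), False
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        iSig = linalg.cho_solve((c, low), np.eye(p), check_finite=False)
        F = logdet + float(np.sum(iSig * S)) - logdet_S - p
        # G = dF/dSigma (up to symmetry); Q embeds it over all variables
        G = iSig - iSig @ S @ iSig
        Q = np.zeros((self.k, self.k))
        Q[:p, :p] = G
        R = M @ Q @ A
        H = A.T @ Q @ A
        grad = np.zeros(self.n_free)
        if self.b_t.size:
            np.add.at(grad, self.b_t, 2.0 * R[self.b_j, self.b_i])
        if self.p_t.size:
            diag = self.p_i == self.p_j
            vals = np.where(
                diag,
                H[self.p_i, self.p_i],
                H[self.p_i, self.p_j] + H[self.p_j, self.p_i],
            )
            np.add.at(grad, self.p_t, vals)
        return F, grad, True

    # -- Jacobian of the implied covariance --------------------------------
    def sigma_jacobian(self, theta: np.ndarray) -> np.ndarray:
        """Stack of d Sigma / d theta_q, shape (n_free, p, p)."""
        p = self.p
        B, Psi = self.assemble(theta)
        A = self.structural_inverse(B)
        M = A @ Psi @ A.T
        P = A[:p, :]  # observed rows of A
        out = np.zeros((self.n_free, p, p))
        for i, j, t in zip(self.b_i, self.b_j, self.b_t):
            d = np.outer(P[:, i], M[j, :p])
            out[t] += d + d.T
        for i, j, t in zip(self.p_i, self.p_j, self.p_t):
            if i == j:
                out[t] += np.outer(P[:, i], P[:, i])
            else:
                out[t] += np.outer(P[:, i], P[:, j]) + np.outer(P[:, j], P[:, i])
        return out

    def candidate_jacobian(
        self, theta: np.ndarray, entries: list[tuple[str, int, int]]
    ) -> np.ndarray:
        """d Sigma / d value for extra (fixed-at-zero) candidate entries."""
        p = self.p
        B, Psi = self.assemble(theta)
        A = self.structural_inverse(B)
        M = A @ Psi @ A.T
        P = A[:p, :]
        out = np.zeros((len(entries), p, p))
        for q, (which, i, j) in enumerate(entries):
            if which == "B":
                d = np.outer(P[:, i], M[j, :p])
                out[q] = d + d.T
            elif i == j:
                out[q] = np.outer(P[:, i], P[:, i])
            else:
                out[q] = np.outer(P[:, i], P[:, j]) + np.outer(P[:, j], P[:, i])
        return out

    def entry_for(self, lhs: str, op: str, rhs: str) -> tuple[str, int, int]:
        idx = {n: i for i, n in enumerate(self.names)}
        if op == LOADING:
            return ("B", idx[rhs], idx[lhs])
        if op == REGRESSION:
            return ("B", idx[lhs], idx[rhs])
        return ("P", idx[lhs], idx[rhs])
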