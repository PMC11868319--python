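"""EM-REML engine on the mixed-model equations.

Fits y = X b + sum_k Z_k u_k + e with u_k ~ N(0, sigma2_k K_k) for known
kernels K_k (identity or a genomic relationship), optionally plus one
factor-analytic genotype-by-environment term u ~ N(0, (T T' + Psi) x G)
(Kronecker, environment-major ordering), and e ~ N(0, sigma2_e I).

Variance parameters are estimated by EM-REML (Henderson's updates from the
inverse of the mixed-model coefficient matrix); the factor-analytic block
uses an inner factor-analysis EM as its conditional maximisation step, so
the overall algorithm is a generalized EM and the restricted log-likelihood
is non-decreasing across iterations.  Incidence matrices are never formed:
each random term is an integer level code per record and the coefficient
matrix is accumulated with scatter-adds.

The restricted likelihood is evaluated through the standard identity

    -2 l_R = (n-p) log 2 pi + (n-p-q) log sigma2_e
             + sum_k (q_k log sigma2_k + log|K_k|) + log|M|
             + (y'y - sol'rhs) / sigma2_e

with M the coefficient matrix [[X'X, X'Z], [Z'X, Z'Z + sigma2_e Gamma^-1]]
and X reduced to full column rank.  A direct dense-covariance evaluation is
used as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, get_lapack_funcs, qr

__all__ = ["RandomTerm", "FaGxETerm", "ConvergenceError", "EmReml", "RemlResult",
           "fa_inner_em"]

_TWO_PI = 2.0 * np.pi


class ConvergenceError(RuntimeError):
    """REML iteration failed; carries the log-likelihood trajectory."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


@dataclass
class RandomTerm:
    """One scalar-variance random term: u ~ N(0, var * K)."""

    name: str
    codes: np.ndarray
    n_levels: int
    K_inv: np.ndarray | None = None
    K_logdet: float = 0.0
    var: float = 1.0

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.intp)
        if self.codes.min() < 0 or self.codes.max() >= self.n_levels:
            raise ValueError(f"term {self.name}: codes outside [0, n_levels)")


@dataclass
class FaGxETerm:
    """Line-by-environment effects with covariance (T T' + Psi) kron G.

    Ordering is environment-major: level = env * n_lines + line.
    """

    name: str
    env_codes: np.ndarray
    line_codes: np.ndarray
    n_env: int
    n_lines: int
    G_inv: np.ndarray
    G_logdet: float
    loadings: np.ndarray = None
    specifics: np.ndarray = None

    def __post_init__(self):
        self.env_codes = np.asarray(self.env_codes, dtype=np.intp)
        self.line_codes = np.asarray(self.line_codes, dtype=np.intp)
        if self.loadings is None:
            self.loadings = np.full(self.n_env, 1.0)
        if self.specifics is None:
            self.specifics = np.full(self.n_env, 1.0)
        self.loadings = np.asarray(self.loadings, float).copy()
        self.specifics = np.asarray(self.specifics, float).copy()

    @property
    def codes(self) -> np.ndarray:
        return self.env_codes * self.n_lines + self.line_codes

    @property
    def n_levels(self) -> int:
        return self.n_env * self.n_lines

    def sigma_env(self) -> np.ndarray:
        t = self.loadings
        return np.outer(t, t) + np.diag(self.specifics)


def fa_inner_em(S: np.ndarray, loadings: np.ndarray, specifics: np.ndarray,
                n_iter: int = 50, tol: float = 1e-10,
                floor: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """One-factor analysis EM (Rubin-Thayer) fitted to a covariance S.

    Each sweep is guaranteed not to decrease the factor-model likelihood of
    S, which keeps the outer REML iteration monotone.  The loading sign is
    fixed by forcing the first entry >= 0.
    """
    t = np.asarray(loadings, float).copy()
    psi = np.maximum(np.asarray(specifics, float).copy(), floor)
    for _ in range(n_iter):
        sigma = np.outer(t, t) + np.diag(psi)
        beta = np.linalg.solve(sigma, t)  # = Sigma^-1 t
        ef2 = 1.0 - beta @ t + beta @ S @ beta
        sb = S @ beta
        t_new = sb / ef2
        psi_new = np.maximum(np.diag(S) - t_new * sb, floor)
        delta = max(np.max(np.abs(t_new - t)), np.max(np.abs(psi_new - psi)))
        t, psi = t_new, psi_new
        if delta < tol * (1.0 + np.max(np.abs(np.diag(S)))):
            break
    if t[0] < 0:
        t = -t
    return t, psi


@dataclass
class RemlResult:
    beta: np.ndarray
    fixed_columns: list
    u: dict
    variances: dict
    sigma2_e: float
    loglik: float
    loglik_trace: list
    converged: bool
    n_iter: int
    n: int
    rank_x: int
    fa_loadings: np.ndarray | None = None
    fa_specifics: np.ndarray | None = None

    def sigma_env(self) -> np.ndarray | None:
        if self.fa_loadings is None:
            return None
        t = self.fa_loadings
        return np.outer(t, t) + np.diag(self.fa_specifics)


class EmReml:
    """Assembles the mixed-model equations once and iterates EM-REML."""

    def __init__(self, y, X, terms, fixed_names=None):
        self.y = np.asarray(y, float)
        X = np.atleast_2d(np.asarray(X, float))
        n = len(self.y)
        if X.shape[0] != n:
            raise ValueError("X and y have different numbers of records")
        if fixed_names is None:
            fixed_names = [f"x{j}" for j in range(X.shape[1])]
        # reduce the fixed design to full column rank (pivoted QR)
        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        rank = int(np.sum(diag > max(X.shape) * np.finfo(float).eps * diag[0])) \
            if diag.size else 0
        keep = sorted(piv[:rank])
        self.X = X[:, keep]
        self.fixed_columns = [fixed_names[j] for j in keep]
        self.dropped_columns = [fixed_names[j] for j in piv[rank:]]
        self.p = rank
        self.terms = [t for t in terms if not isinstance(t, FaGxETerm)]
        fa = [t for t in terms if isinstance(t, FaGxETerm)]
        if len(fa) > 1:
            raise ValueError("at most one factor-analytic term is supported")
        self.fa = fa[0] if fa else None
        self.n = n
        self._assemble()

    # -- structural parts (variance-free) ---------------------------------
    def _assemble(self):
        p = self.p
        offs, q = [], 0
        all_terms = list(self.terms) + ([self.fa] if self.fa else [])
        for t in all_terms:
            offs.append(p + q)
            q += t.n_levels
        self.offsets = offs
        self.q_tot = q
        d = p + q
        M0 = np.zeros((d, d))
        M0[:p, :p] = self.X.T @ self.X
        rhs = np.zeros(d)
        rhs[:p] = self.X.T @ self.y
        # fill the lower triangle only (same-term Z'Z blocks are diagonal,
        # cross-term blocks go below the diagonal), then mirror once
        for t, off in zip(all_terms, offs):
            codes = t.codes
            for j in range(p):
                np.add.at(M0[:, j], off + codes, self.X[:, j])
            np.add.at(rhs, off + codes, self.y)
        for a, (ta, offa) in enumerate(zip(all_terms, offs)):
            for tb, offb in list(zip(all_terms, offs))[:a + 1]:
                np.add.at(M0, (offa + ta.codes, offb + tb.codes), 1.0)
        M0 = np.tril(M0) + np.tril(M0, -1).T
        self.M0 = M0
        self.rhs = rhs
        self.yty = float(self.y @ self.y)
        self._all_terms = all_terms

    # -- one solve at the current variance parameters ---------------------
    def _solve(self, sigma2_e, need_inverse):
        M = self.M0.copy()
        logdet_k = 0.0
        for t, off in zip(self._all_terms, self.offsets):
            sl = slice(off, off + t.n_levels)
            if isinstance(t, FaGxETerm):
                sigma = t.sigma_env()
                sig_inv = np.linalg.inv(sigma)
                M[sl, sl] += sigma2_e * np.kron(sig_inv, t.G_inv)
                sign, ld = np.linalg.slogdet(sigma)
                logdet_k += t.n_lines * ld + t.n_env * t.G_logdet
            else:
                if t.K_inv is None:
                    M[sl, sl][np.diag_indices(t.n_levels)] += sigma2_e / t.var
                else:
                    M[sl, sl] += (sigma2_e / t.var) * t.K_inv
                logdet_k += t.n_levels * np.log(t.var) + t.K_logdet
        try:
            cf = cho_factor(M, lower=True, overwrite_a=True, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"mixed-model equations not positive definite: {exc}") from exc
        sol = cho_solve(cf, self.rhs, check_finite=False)
        logdet_m = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        equad = self.yty - float(sol @ self.rhs)
        np_, q = self.n - self.p, self.q_tot
        m2l = (np_ * np.log(_TWO_PI) + (np_ - q) * np.log(sigma2_e)
               + logdet_k + logdet_m + equad / sigma2_e)
        Cinv = None
        if need_inverse:
            potri, = get_lapack_funcs(("potri",), (M,))
            Cinv, info = potri(cf[0], lower=True, overwrite_c=False)
            if info != 0:
                raise ConvergenceError(f"dpotri failed with info={info}")
            Cinv = np.tril(Cinv) + np.tril(Cinv, -1).T
        return sol, -0.5 * m2l, equad, Cinv

    # -- EM iteration ------------------------------------------------------
    def run(self, tol: float = 1e-6, max_iter: int = 500, estimate: bool = True,
            sigma2_e: float | None = None,
            require_convergence: bool = True) -> RemlResult:
        if sigma2_e is None:
            sigma2_e = 0.5 * float(np.var(self.y)) or 1.0
        var_floor = 1e-8 * max(float(np.var(self.y)), 1e-12)
        trace = []
        converged = not estimate
        it = 0
        if estimate:
            for it in range(1, max_iter + 1):
                sol, ll, equad, Cinv = self._solve(sigma2_e, need_inverse=True)
                trace.append(ll)
                for t, off in zip(self._all_terms, self.offsets):
                    sl = slice(off, off + t.n_levels)
                    u = sol[sl]
                    C = Cinv[sl, sl]
                    if isinstance(t, FaGxETerm):
                        ne, nl = t.n_env, t.n_lines
                        U = u.reshape(ne, nl).T  # lines x envs
                        C4 = C.reshape(ne, nl, ne, nl)
                        Tc = np.einsum("kl,ikjl->ij", t.G_inv, C4)
                        S = (U.T @ t.G_inv @ U + sigma2_e * Tc) / nl
                        S = 0.5 * (S + S.T)
                        t.loadings, t.specifics = fa_inner_em(
                            S, t.loadings, t.specifics, floor=var_floor)
                    else:
                        if t.K_inv is None:
                            quad = float(u @ u)
                            tr = float(np.trace(C))
                        else:
                            quad = float(u @ t.K_inv @ u)
                            tr = float(np.sum(t.K_inv * C))
                        t.var = max((quad + sigma2_e * tr) / t.n_levels, var_floor)
                sigma2_e = max(equad / (self.n - self.p), var_floor)
                if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                    converged = True
                    break
            if not converged and require_convergence:
                last = trace[-1] - trace[-2] if len(trace) > 1 else float("nan")
                raise ConvergenceError(
                    f"EM-REML did not converge in {max_iter} iterations "
                    f"(last change {last:.3e})", trace)
        # final solve at the returned parameter values
        sol, ll, _, _ = self._solve(sigma2_e, need_inverse=False)
        trace.append(ll)
        u_out, variances = {}, {}
        for t, off in zip(self._all_terms, self.offsets):
            u_out[t.name] = sol[off:off + t.n_levels].copy()
            if not isinstance(t, FaGxETerm):
                variances[t.name] = t.var
        fa_t = self.fa.loadings.copy() if self.fa else None
        fa_p = self.fa.specifics.copy() if self.fa else None
        return RemlResult(beta=sol[:self.p].copy(),
                          fixed_columns=list(self.fixed_columns),
                          u=u_out, variances=variances, sigma2_e=sigma2_e,
                          loglik=ll, loglik_trace=trace, converged=converged,
                          n_iter=it, n=self.n, rank_x=self.p,
                          fa_loadings=fa_t, fa_specifics=fa_p)
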