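"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (explicit loops, plain inv/eig) and
shares no code path with the package implementation it checks.
"""

import numpy as np
from scipy.linalg import qr


def naive_vanraden(calls):
    """VanRaden G by explicit loops over line pairs."""
    calls = np.asarray(calls, float)
    n, m = calls.shape
    p = calls.mean(axis=0)
    denom = 2.0 * sum(pj * (1 - pj) for pj in p)
    Z = calls - p
    G = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            G[i, j] = float(Z[i] @ Z[j]) / denom
    return G


def naive_distance(calls):
    calls = np.asarray(calls, float)
    n = calls.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.sqrt(np.sum((calls[i] - calls[j]) ** 2))
    return D


def naive_rms(P, Dst, train_idx, test_idx, lam):
    """All eight relationship measures by dense linear algebra."""
    P_T = P[list(train_idx)]
    P_V = P[list(test_idx)]
    k = P.shape[1]
    A = P_T.T @ P_T + lam * np.eye(k)
    Ainv = np.linalg.inv(A)
    PEV = P_V @ Ainv @ P_V.T
    diag = np.diag(PEV)
    norms = np.array([p @ p for p in P_V])
    cd = 1.0 - lam * diag / (norms + lam)
    cd = np.where(norms == 0, 0.0, cd)
    sub = Dst[np.ix_(list(train_idx), list(test_idx))]
    return {
        "PEVMEAN": diag.mean(),
        "PEVMAX": diag.max(),
        "DOPT": np.linalg.slogdet(PEV + 1e-12 * np.eye(len(diag)))[1],
        "GOPTPEV": np.linalg.eigvalsh(PEV).max(),
        "AOPT": np.trace(Ainv),
        "CDMEAN": cd.mean(),
        "CDMAX": cd.max(),
        "NDT": -sub.mean(),
    }


def dense_reml_loglik(y, X, terms, sigma2_e, fa=None):
    """Restricted log-likelihood via the marginal covariance V.

    ``terms`` are mixedmodel.RandomTerm objects; ``fa`` an optional
    FaGxETerm.  Used to cross-check the engine's MME-based evaluation.
    """
    y = np.asarray(y, float)
    n = len(y)
    _, R, piv = qr(np.atleast_2d(X), mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    rank = int(np.sum(d > max(np.shape(X)) * np.finfo(float).eps * d[0]))
    Xr = np.atleast_2d(X)[:, sorted(piv[:rank])]
    V = sigma2_e * np.eye(n)
    for t in terms:
        Z = np.eye(t.n_levels)[t.codes]
        K = np.eye(t.n_levels) if t.K_inv is None else np.linalg.inv(t.K_inv)
        V += t.var * Z @ K @ Z.T
    if fa is not None:
        Z = np.eye(fa.n_levels)[fa.codes]
        G = np.linalg.inv(fa.G_inv)
        K = np.kron(fa.sigma_env(), G)
        V += Z @ K @ Z.T
    Vi = np.linalg.inv(V)
    XtViX = Xr.T @ Vi @ Xr
    Pm = Vi - Vi @ Xr @ np.linalg.solve(XtViX, Xr.T @ Vi)
    ld_V = np.linalg.slogdet(V)[1]
    ld_X = np.linalg.slogdet(XtViX)[1]
    p = Xr.shape[1]
    return -0.5 * ((n - p) * np.log(2 * np.pi) + ld_V + ld_X + y @ Pm @ y)


def assert_monotone_loglik(trace, tol=1e-6):
    diffs = np.diff(np.asarray(trace))
    assert (diffs > -tol * (1.0 + np.abs(trace[0]))).all(), \
        f"log-likelihood decreased: min step {diffs.min():.3e}"
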