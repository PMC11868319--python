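"""Training/testing-set relationship measures from PCA scores of G.

Eight optimal-design style criteria quantifying how well the full set
(training) represents the sparse lines (testing), computed from the
principal-component scores P of the genomic relationship matrix and the
marker distance matrix, with ridge shrinkage lambda (default 1e-5).

The prediction error variance (PEV) matrix over the test lines is

    PEV = P_V (P_T' P_T + lambda I)^-1 P_V'

with P_T, P_V the training/test rows of P.  Summaries: PEVMEAN/PEVMAX
(mean/max diagonal), DOPT (log determinant), GOPTPEV (largest eigenvalue),
AOPT (trace of the inverse training information matrix), CDMEAN/CDMAX
(mean/max reliability CD_i = 1 - lambda PEV_ii / (p_i'p_i + lambda)), and
NDT (negated mean marker distance between training and test lines, so that
larger means genetically closer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "RmVector",
    "pev_matrix",
    "rm_pev_summaries",
    "rm_cd",
    "rm_aopt_goptpev",
    "rm_neg_dist",
    "compute_all_rms",
]

RM_NAMES = ("PEVMEAN", "PEVMAX", "DOPT", "GOPTPEV", "AOPT",
            "CDMEAN", "CDMAX", "NDT")

_DOPT_JITTER = 1e-12


@dataclass
class RmVector:
    PEVMEAN: float
    PEVMAX: float
    DOPT: float
    GOPTPEV: float
    AOPT: float
    CDMEAN: float
    CDMAX: float
    NDT: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in RM_NAMES}


def _index_rows(P, line_ids, wanted):
    pos = {l: i for i, l in enumerate(line_ids)}
    missing = [l for l in wanted if l not in pos]
    if missing:
        raise KeyError(f"lines not in score matrix: {missing[:5]}")
    return P[[pos[l] for l in wanted]]


def _train_info_chol(P_T, lam):
    k = P_T.shape[1]
    A = P_T.T @ P_T + lam * np.eye(k)
    return cho_factor(A, lower=True)


def pev_matrix(P_T: np.ndarray, P_V: np.ndarray, lam: float = 1e-5) -> np.ndarray:
    """PEV = P_V (P_T'P_T + lam I)^-1 P_V' (symmetric PSD, test x test)."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if P_T.shape[0] < 1 or P_V.shape[0] < 1:
        raise ValueError("training and test sets must be nonempty")
    cf = _train_info_chol(P_T, lam)
    pev = P_V @ cho_solve(cf, P_V.T)
    return 0.5 * (pev + pev.T)


def rm_pev_summaries(P_T, P_V, lam: float = 1e-5) -> tuple[float, float, float]:
    """(PEVMEAN, PEVMAX, DOPT) from the PEV matrix."""
    pev = pev_matrix(P_T, P_V, lam)
    d = np.diag(pev)
    sign, logdet = np.linalg.slogdet(pev + _DOPT_JITTER * np.eye(len(d)))
    return float(d.mean()), float(d.max()), float(logdet)


def rm_cd(P_T, P_V, lam: float = 1e-5) -> tuple[float, float]:
    """(CDMEAN, CDMAX); each CD_i = 1 - lam * PEV_ii / (p_i'p_i + lam) in [0,1]."""
    pev = pev_matrix(P_T, P_V, lam)
    norms = np.einsum("ij,ij->i", P_V, P_V)
    cd = 1.0 - lam * np.diag(pev) / (norms + lam)
    cd = np.where(norms == 0.0, 0.0, cd)
    return float(cd.mean()), float(cd.max())


def rm_aopt_goptpev(P_T, P_V, lam: float = 1e-5) -> tuple[float, float]:
    """AOPT = tr((P_T'P_T + lam I)^-1); GOPTPEV = largest eigenvalue of PEV."""
    cf = _train_info_chol(P_T, lam)
    k = P_T.shape[1]
    aopt = float(np.trace(cho_solve(cf, np.eye(k))))
    pev = pev_matrix(P_T, P_V, lam)
    gopt = float(np.linalg.eigvalsh(pev)[-1])
    return aopt, gopt


def rm_neg_dist(Dst: np.ndarray, train_idx, test_idx) -> float:
    """Negated mean distance over all training-test pairs."""
    sub = Dst[np.ix_(train_idx, test_idx)]
    return float(-sub.mean())


def compute_all_rms(P, Dst: np.ndarray, alloc, lam: float = 1e-5,
                    per_ss_mean: bool = False) -> RmVector:
    """All eight relationship measures for one allocation.

    Training set = full-set lines; test set = union of all sparse lines
    (the measures depend only on the line partition, not on which
    environments are masked).  ``P`` is a PcaScores object or a plain
    (scores, line_ids) pair; Dst is indexed like the score rows.
    With per_ss_mean, the PEV/CD summaries are averaged per sparse set.
    """
    if hasattr(P, "P"):
        scores, line_ids = P.P, list(P.line_ids)
    else:
        scores, line_ids = P
        line_ids = list(line_ids)
    train = list(alloc.full_set)
    test_sets = [list(s) for s in alloc.sparse_sets]
    test = [l for s in test_sets for l in s]
    if not train or not test:
        raise ValueError("training and test sets must both be nonempty")
    P_T = _index_rows(scores, line_ids, train)
    pos = {l: i for i, l in enumerate(line_ids)}
    tr_idx = [pos[l] for l in train]
    te_idx = [pos[l] for l in test]
    groups = test_sets if per_ss_mean else [test]
    parts = []
    for grp in groups:
        P_V = _index_rows(scores, line_ids, grp)
        pm, px, dopt = rm_pev_summaries(P_T, P_V, lam)
        cdm, cdx = rm_cd(P_T, P_V, lam)
        aopt, gopt = rm_aopt_goptpev(P_T, P_V, lam)
        parts.append((pm, px, dopt, gopt, aopt, cdm, cdx))
    pm, px, dopt, gopt, aopt, cdm, cdx = np.mean(parts, axis=0)
    ndt = rm_neg_dist(Dst, tr_idx, te_idx)
    return RmVector(PEVMEAN=float(pm), PEVMAX=float(px), DOPT=float(dopt),
                    GOPTPEV=float(gopt), AOPT=float(aopt), CDMEAN=float(cdm),
                    CDMAX=float(cdx), NDT=ndt)
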