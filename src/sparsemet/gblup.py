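"""GBLUP with factor-analytic or reaction-norm genotype-by-environment terms.

Predicts every line x tester x environment cell — including cells masked by
a sparse design — from adjusted phenotypes and a conditioned genomic
relationship matrix.  Two covariance modes for the line-by-environment
effects:

FA1  u ~ N(0, (T T' + Psi) kron G): a one-factor model for the
     between-environment genetic covariance, estimated by EM-REML.
RN   reaction norm: an iid-across-environments genomic interaction on top
     of a genomic line main effect, i.e. the record-level kernel
     (Z_g G Z_g') o (Z_s Z_s') sigma2_LS — the Hadamard product of the
     genomic and environment incidence kernels — which is the special case
     Sigma_E = sigma2_main 11' + sigma2_LS I of FA1.

Tester and environment x tester and line x tester effects are iid
scalar-variance terms; the residual is homogeneous.

"Observed" breeding values (OBV) come from the complete-data fit and
predicted breeding values (PBV) from the masked fit; per-line values are
the mean over environments of the line-by-environment BLUPs plus the mean
over testers of the line x tester BLUPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm import GenomicRelationship
from .mixedmodel import EmReml, FaGxETerm, RandomTerm, RemlResult

__all__ = ["GblupFit", "FaStructure", "BreedingValues", "fit_gblup",
           "plugin_params", "breeding_values"]


@dataclass
class FaStructure:
    """Estimated loadings/specific variances and the implied env covariance."""

    loadings: np.ndarray
    specifics: np.ndarray

    def sigma_env(self) -> np.ndarray:
        return np.outer(self.loadings, self.loadings) + np.diag(self.specifics)


@dataclass
class GblupFit:
    mode: str
    line_ids: list
    testers: list
    environments: list
    result: RemlResult
    line_env: np.ndarray      # n_lines x n_env total genomic BLUP per env
    line_tester: np.ndarray   # n_lines x n_testers
    tester_eff: np.ndarray
    env_tester: np.ndarray    # n_env x n_testers
    env_fixed: np.ndarray     # fixed environment effects incl. intercept
    fa: FaStructure | None = None

    @property
    def variances(self) -> dict:
        v = dict(self.result.variances)
        v["residual"] = self.result.sigma2_e
        return v

    def line_values(self) -> np.ndarray:
        """Per-line breeding value: mean over envs + mean over testers."""
        return self.line_env.mean(axis=1) + self.line_tester.mean(axis=1)

    def cell_predictions(self) -> pd.DataFrame:
        """Predicted value for every cell of the full grid, masked or not."""
        n, t, m = len(self.line_ids), len(self.testers), len(self.environments)
        pred = (self.env_fixed[None, None, :]
                + self.tester_eff[None, :, None]
                + self.env_tester.T[None, :, :]
                + self.line_tester[:, :, None]
                + self.line_env[:, None, :])
        rows = []
        for i in range(n):
            for j in range(t):
                for k in range(m):
                    rows.append((self.line_ids[i], self.testers[j],
                                 self.environments[k], pred[i, j, k]))
        return pd.DataFrame(rows, columns=["line", "tester", "env", "value"])


def _empirical_fa_init(adjusted: pd.DataFrame, envs: list,
                       var_y: float) -> tuple[np.ndarray, np.ndarray]:
    """Loadings from the first eigenvector of the phenotypic env covariance."""
    m = len(envs)
    try:
        wide = (adjusted.groupby(["line", "env"], observed=True)["value"]
                .mean().unstack("env").reindex(columns=envs))
        cov = wide.cov(min_periods=2).to_numpy()
        if np.isnan(cov).any():
            raise ValueError
        w, v = np.linalg.eigh(cov)
        lead = v[:, -1] * np.sqrt(max(w[-1], 1e-8))
        if lead.sum() < 0:
            lead = -lead
        loadings = np.abs(lead) + 1e-3 * np.sqrt(var_y)
        specifics = np.maximum(np.diag(cov) - loadings ** 2,
                               0.05 * var_y)
        return loadings, specifics
    except Exception:
        return (np.full(m, np.sqrt(0.3 * var_y)), np.full(m, 0.2 * var_y))


def fit_gblup(adjusted: pd.DataFrame, g: GenomicRelationship,
              mode: str = "FA1", tol: float = 1e-6, max_iter: int = 1000,
              params: dict | None = None,
              require_convergence: bool = True) -> GblupFit:
    """Fit the genomic prediction model on (possibly masked) adjusted values.

    ``params`` fixes the variance parameters (plug-in prediction, e.g. the
    components from a complete-data fit applied to a masked table): a dict
    with the scalar term variances, "sigma2_e", and in FA1 mode
    "fa_loadings"/"fa_specifics".  Without it, all parameters are estimated
    by EM-REML.
    """
    if mode not in ("FA1", "RN"):
        raise ValueError("mode must be 'FA1' or 'RN'")
    if g.G_inv is None:
        raise ValueError("GenomicRelationship must be conditioned and "
                         "inverted first (condition_and_invert)")
    if len(adjusted) == 0:
        raise ValueError("no records to fit")
    line_ids = list(g.line_ids)
    testers = sorted(adjusted["tester"].unique())
    envs = sorted(adjusted["env"].unique())
    n, t, m = len(line_ids), len(testers), len(envs)
    counts = adjusted["env"].value_counts()
    empty = [e for e in envs if counts.get(e, 0) == 0]
    if empty:  # pragma: no cover - sorted-unique envs always have records
        raise ValueError(f"environments without records: {empty}")

    line_pos = {l: i for i, l in enumerate(line_ids)}
    unknown = set(adjusted["line"]) - set(line_pos)
    if unknown:
        raise ValueError(f"records for lines missing from G: "
                         f"{sorted(unknown)[:5]}")
    lc = adjusted["line"].map(line_pos).to_numpy(np.intp)
    tc = adjusted["tester"].map({x: i for i, x in enumerate(testers)}
                                ).to_numpy(np.intp)
    ec = adjusted["env"].map({x: i for i, x in enumerate(envs)}
                             ).to_numpy(np.intp)
    y = adjusted["value"].to_numpy(float)
    var_y = float(np.var(y)) or 1.0

    X = np.zeros((len(y), m))
    X[:, 0] = 1.0
    for k in range(1, m):
        X[:, k] = ec == k
    fixed_names = ["intercept"] + [f"env[{e}]" for e in envs[1:]]

    v0 = 0.1 * var_y
    terms: list = [
        RandomTerm("tester", tc, t, var=v0),
        RandomTerm("env:tester", ec * t + tc, m * t, var=v0),
        RandomTerm("line:tester", lc * t + tc, n * t, var=v0),
    ]
    if mode == "FA1":
        t0, p0 = _empirical_fa_init(adjusted, envs, var_y)
        fa = FaGxETerm("line:env", ec, lc, m, n, g.G_inv, g.logdet_cond,
                       loadings=t0, specifics=p0)
        terms.append(fa)
    else:
        terms.append(RandomTerm("line", lc, n, K_inv=g.G_inv,
                                K_logdet=g.logdet_cond, var=0.3 * var_y))
        terms.append(RandomTerm("line:env", ec * n + lc, m * n,
                                K_inv=np.kron(np.eye(m), g.G_inv),
                                K_logdet=m * g.logdet_cond, var=0.2 * var_y))

    sigma2_e = None
    estimate = params is None
    if params is not None:
        sigma2_e = params["sigma2_e"]
        for term in terms:
            if isinstance(term, FaGxETerm):
                term.loadings = np.asarray(params["fa_loadings"], float).copy()
                term.specifics = np.asarray(params["fa_specifics"], float).copy()
            else:
                term.var = params[term.name]

    engine = EmReml(y, X, terms, fixed_names=fixed_names)
    result = engine.run(tol=tol, max_iter=max_iter, estimate=estimate,
                        sigma2_e=sigma2_e,
                        require_convergence=require_convergence)

    # unpack BLUPs onto the full grid
    tester_eff = result.u["tester"]
    env_tester = result.u["env:tester"].reshape(m, t)
    line_tester = result.u["line:tester"].reshape(n, t)
    if mode == "FA1":
        line_env = result.u["line:env"].reshape(m, n).T
        fa_struct = FaStructure(result.fa_loadings, result.fa_specifics)
    else:
        line_env = (result.u["line"][:, None]
                    + result.u["line:env"].reshape(m, n).T)
        fa_struct = None
    env_fixed = np.zeros(m)
    for j, name in enumerate(result.fixed_columns):
        if name == "intercept":
            env_fixed += result.beta[j]
        elif name.startswith("env["):
            env = name[4:-1]
            env_fixed[envs.index(env)] += result.beta[j]
    return GblupFit(mode=mode, line_ids=line_ids, testers=testers,
                    environments=envs, result=result, line_env=line_env,
                    line_tester=line_tester, tester_eff=tester_eff,
                    env_tester=env_tester, env_fixed=env_fixed, fa=fa_struct)


def plugin_params(fit: GblupFit) -> dict:
    """Variance parameters of a fit, in the form fit_gblup(params=...) expects."""
    p = {name: v for name, v in fit.result.variances.items()}
    p["sigma2_e"] = fit.result.sigma2_e
    if fit.mode == "FA1":
        p["fa_loadings"] = fit.fa.loadings
        p["fa_specifics"] = fit.fa.specifics
    return p


@dataclass
class BreedingValues:
    """Per-line observed (complete-data) and predicted (masked) values."""

    line_ids: list
    obv: np.ndarray
    pbv: np.ndarray
    obv_line_env: np.ndarray
    pbv_line_env: np.ndarray

    def __post_init__(self):
        if not (np.isfinite(self.obv).all() and np.isfinite(self.pbv).all()):
            raise ValueError("breeding values must be finite")


def breeding_values(complete_fit: GblupFit, masked_fit: GblupFit
                    ) -> BreedingValues:
    """Pair the complete-data and masked-data per-line predictions."""
    if list(complete_fit.line_ids) != list(masked_fit.line_ids):
        raise ValueError("fits cover different line sets")
    return BreedingValues(
        line_ids=list(complete_fit.line_ids),
        obv=complete_fit.line_values(),
        pbv=masked_fit.line_values(),
        obv_line_env=complete_fit.line_env.copy(),
        pbv_line_env=masked_fit.line_env.copy())
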