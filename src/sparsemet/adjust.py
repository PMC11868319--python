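"""Plot-level phenotype adjustment and broad-sense heritability.

The plot model for a multi-environment testcross trial treats environment
(S), experiment (E), their interaction and replicate-within-S.E as fixed
design effects, and block-within-replicate, line, tester and all their
interactions with environment as random.  Adjusted line x tester x
environment values are the observations minus the estimated design effects
and block BLUPs, averaged over replicates — the response passed on to the
genomic prediction stage.

Broad-sense heritability on an entry-mean basis uses the variance
components from a refit with every term random:

    H^2 = V_L / (V_L + V_LxE/m + V_LT/t + V_LTE/(t m) + V_R/(t m r))
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixedmodel import EmReml, RandomTerm, RemlResult

__all__ = [
    "HeritabilityComponents",
    "AdjustmentFit",
    "fit_adjustment_model",
    "adjusted_values",
    "heritability",
]

REQUIRED_COLUMNS = ("env", "experiment", "rep", "block", "line", "tester", "value")


@dataclass
class HeritabilityComponents:
    """Variance components and trial dimensions entering the H^2 formula."""

    V_L: float
    V_LxE: float
    V_LT: float
    V_LTE: float
    V_R: float
    m: int  # environments
    t: int  # testers
    r: int  # replicates

    def __post_init__(self):
        for name in ("V_L", "V_LxE", "V_LT", "V_LTE", "V_R"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.m, self.t, self.r) < 1:
            raise ValueError("m, t, r must all be >= 1")


def heritability(c: HeritabilityComponents) -> float:
    """Entry-mean broad-sense heritability from the variance components."""
    vp = (c.V_L + c.V_LxE / c.m + c.V_LT / c.t + c.V_LTE / (c.t * c.m)
          + c.V_R / (c.t * c.m * c.r))
    if vp <= 0:
        raise ValueError("phenotypic variance is zero; H^2 undefined")
    return c.V_L / vp


def _combo(df: pd.DataFrame, cols) -> pd.Series:
    s = df[cols[0]].astype(str)
    for c in cols[1:]:
        s = s + ":" + df[c].astype(str)
    return s


def _codes(series: pd.Series) -> tuple[np.ndarray, list]:
    codes, levels = pd.factorize(series, sort=True)
    return codes.astype(np.intp), list(levels)


def _dummies(series: pd.Series, label: str, drop_first: bool = True):
    codes, levels = _codes(series)
    start = 1 if drop_first and len(levels) > 1 else 0
    cols = np.zeros((len(series), len(levels) - start))
    for j, lev in enumerate(levels[start:]):
        cols[:, j] = codes == (j + start)
    names = [f"{label}[{lev}]" for lev in levels[start:]]
    return cols, names


# (term name, columns defining the factor) for the random side of the model
_RANDOM_TERMS = [
    ("block", ("env", "experiment", "rep", "block")),
    ("line", ("line",)),
    ("tester", ("tester",)),
    ("line:tester", ("line", "tester")),
    ("env:line", ("env", "line")),
    ("env:tester", ("env", "tester")),
    ("env:line:tester", ("env", "line", "tester")),
]

_FIXED_TERMS = [
    ("env", ("env",)),
    ("experiment", ("experiment",)),
    ("env:experiment", ("env", "experiment")),
    ("rep", ("env", "experiment", "rep")),
]


@dataclass
class AdjustmentFit:
    """REML fit of the plot model plus cached per-record effect estimates."""

    result: RemlResult
    all_random: bool
    design_effect: np.ndarray  # fitted fixed design effects (minus intercept)
    block_blup: np.ndarray     # block BLUP per plot record
    n_env: int
    n_testers: int
    n_reps: int
    index: pd.Index

    @property
    def variances(self) -> dict:
        v = dict(self.result.variances)
        v["residual"] = self.result.sigma2_e
        return v

    def heritability_components(self) -> HeritabilityComponents:
        """Map the fitted components onto the H^2 formula (all-random refit)."""
        v = self.result.variances
        return HeritabilityComponents(
            V_L=v["line"], V_LxE=v["env:line"], V_LT=v["line:tester"],
            V_LTE=v["env:line:tester"], V_R=self.result.sigma2_e,
            m=self.n_env, t=self.n_testers, r=self.n_reps)


def fit_adjustment_model(pheno: pd.DataFrame, all_random: bool = False,
                         tol: float = 1e-6, max_iter: int = 500,
                         require_convergence: bool = True) -> AdjustmentFit:
    """EM-REML fit of the plot-level mixed model.

    With all_random=True the design terms (environment, experiment, their
    interaction, replicate) are moved to the random side as well — the
    parameterization under which the heritability components are reported.
    Aliased fixed columns are dropped automatically (nested codings are
    rank-deficient by construction) and recorded on the fit.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    pheno = pheno.reset_index(drop=True)
    y = pheno["value"].to_numpy(float)
    n = len(y)

    fixed_blocks = [(np.ones((n, 1)), ["intercept"])]
    random_specs = list(_RANDOM_TERMS)
    if all_random:
        random_specs = [(name, cols) for name, cols in _FIXED_TERMS] + random_specs
    else:
        for name, cols in _FIXED_TERMS:
            fixed_blocks.append(_dummies(_combo(pheno, cols), name))
    X = np.hstack([b for b, _ in fixed_blocks])
    names = [nm for _, ns in fixed_blocks for nm in ns]

    terms = []
    for name, cols in random_specs:
        codes, levels = _codes(_combo(pheno, cols))
        if len(levels) < 2:
            if all_random and name in dict(_FIXED_TERMS):
                # a single-level design factor carries no variance; it is
                # absorbed by the intercept in the all-random refit
                warnings.warn(f"skipping single-level term {name!r}",
                              stacklevel=2)
                continue
            raise ValueError(f"random term {name!r} has fewer than 2 levels")
        terms.append(RandomTerm(name, codes, len(levels),
                                var=0.1 * float(np.var(y)) or 1.0))

    engine = EmReml(y, X, terms, fixed_names=names)
    result = engine.run(tol=tol, max_iter=max_iter,
                        require_convergence=require_convergence)

    # per-record design effects (kept fixed columns except the intercept)
    kept = result.fixed_columns
    beta = result.beta
    design = np.zeros(n)
    if "intercept" in kept:
        non_int = [i for i, nm in enumerate(kept) if nm != "intercept"]
    else:  # pragma: no cover - intercept always has the largest column norm
        non_int = list(range(len(kept)))
    for i in non_int:
        design += beta[i] * engine.X[:, i]
    block_term = next(t for t in terms if t.name == "block")
    block = result.u["block"][block_term.codes]

    return AdjustmentFit(
        result=result, all_random=all_random, design_effect=design,
        block_blup=block, n_env=pheno["env"].nunique(),
        n_testers=pheno["tester"].nunique(), n_reps=pheno["rep"].nunique(),
        index=pheno.index)


def adjusted_values(fit: AdjustmentFit, pheno: pd.DataFrame) -> pd.DataFrame:
    """Observations minus design effects and block BLUPs, averaged over reps.

    Returns a tidy (line, tester, env, value) table covering the complete
    grid; raises if any cell has no observation.
    """
    pheno = pheno.reset_index(drop=True)
    if len(pheno) != len(fit.design_effect):
        raise ValueError("phenotype table does not match the fitted model")
    adj = pheno["value"].to_numpy(float) - fit.design_effect - fit.block_blup
    out = pheno[["line", "tester", "env"]].copy()
    out["value"] = adj
    cells = out.groupby(["line", "tester", "env"], sort=True, observed=True)
    table = cells["value"].mean().reset_index()
    full = (out["line"].nunique() * out["tester"].nunique()
            * out["env"].nunique())
    if len(table) != full:
        raise ValueError("phenotype table does not cover the full "
                         "line x tester x env grid")
    return table
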