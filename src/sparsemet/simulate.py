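"""Synthetic marker and multi-environment testcross trial generator.

Emulates the data structure of a doubled-haploid testcross trial: a 0/1
dominant marker matrix with continuous allele frequencies, latent line
genetic values whose between-environment covariance follows a one-factor
factor-analytic structure (T T' + Psi) kron G, tester and line x tester
effects, and plot-level phenotypes with experiment / replicate / block
design effects and residual noise calibrated so that the entry-mean
heritability hits a configured target.

Trait presets reproduce the heritability ladder of a tropical maize trial:
grain yield 0.75, ears per plant 0.64, plant height 0.93, ear height 0.91.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .adjust import HeritabilityComponents, heritability
from .grm import GenomicRelationship, MarkerMatrix

__all__ = [
    "SimConfig",
    "TrueGeneticValues",
    "TRAIT_H2",
    "components_for_h2",
    "simulate_marker_matrix",
    "simulate_true_values",
    "simulate_trial",
    "write_phenotypes",
]

TRAIT_H2 = {"GY": 0.75, "EPP": 0.64, "PH": 0.93, "EH": 0.91}

# Non-line components in the proportions 2.5 : 0.6 : 1.5 : 6.0, which
# contribute exactly 1.0 to the entry-mean denominator at m=5, t=3, r=2.
_BASE_NONLINE = {"V_LxE": 2.5, "V_LT": 0.6, "V_LTE": 1.5, "V_R": 6.0}


def components_for_h2(h2: float, m: int = 5, t: int = 3, r: int = 2,
                      V_L: float = 3.0) -> HeritabilityComponents:
    """Variance components whose plug-in entry-mean H^2 equals the target.

    The non-line components keep fixed proportions and are scaled jointly;
    at the grain-yield target of 0.75 with m=5, t=3, r=2 they equal
    (2.5, 0.6, 1.5, 6.0) with V_L = 3.0 exactly.
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError(f"target H^2 must be in (0, 1], got {h2}")
    base = (_BASE_NONLINE["V_LxE"] / m + _BASE_NONLINE["V_LT"] / t
            + _BASE_NONLINE["V_LTE"] / (t * m)
            + _BASE_NONLINE["V_R"] / (t * m * r))
    scale = 0.0 if h2 == 1.0 else V_L * (1.0 - h2) / h2 / base
    return HeritabilityComponents(
        V_L=V_L, V_LxE=scale * _BASE_NONLINE["V_LxE"],
        V_LT=scale * _BASE_NONLINE["V_LT"],
        V_LTE=scale * _BASE_NONLINE["V_LTE"],
        V_R=scale * _BASE_NONLINE["V_R"], m=m, t=t, r=r)


@dataclass
class SimConfig:
    """Dimensions, variance targets and noise layout of one simulated trial."""

    n_lines: int = 304
    n_testers: int = 3
    n_environments: int = 5
    n_experiments_per_env: int = 7
    n_reps: int = 2
    blocks_per_rep: int = 24
    n_markers: int = 4489
    allele_freq_law: tuple = ("uniform", 0.02, 0.98)
    var_components: HeritabilityComponents | None = None
    fa_loadings: np.ndarray | None = None
    fa_specific: np.ndarray | None = None
    tester_var: float = 0.25
    env_tester_var: float = 0.10
    design_effect_sd: float = 1.0
    block_var: float = 0.5
    mu: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_lines", "n_testers", "n_environments",
                     "n_experiments_per_env", "n_reps", "blocks_per_rep",
                     "n_markers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.var_components is None:
            self.var_components = components_for_h2(
                TRAIT_H2["GY"], m=self.n_environments, t=self.n_testers,
                r=self.n_reps)
        if self.fa_loadings is not None:
            self.fa_loadings = np.asarray(self.fa_loadings, float)
            if len(self.fa_loadings) != self.n_environments:
                raise ValueError("fa_loadings length must equal n_environments")
        if self.fa_specific is not None:
            self.fa_specific = np.asarray(self.fa_specific, float)
            if len(self.fa_specific) != self.n_environments:
                raise ValueError("fa_specific length must equal n_environments")
            if (self.fa_specific < 0).any():
                raise ValueError("fa_specific entries must be >= 0")

    @classmethod
    def for_trait(cls, trait: str, **kwargs) -> "SimConfig":
        cfg = cls(**kwargs)
        cfg.var_components = components_for_h2(
            TRAIT_H2[trait], m=cfg.n_environments, t=cfg.n_testers,
            r=cfg.n_reps)
        return cfg

    def env_covariance(self) -> np.ndarray:
        """Between-environment genetic covariance T T' + Psi."""
        m = self.n_environments
        t = (self.fa_loadings if self.fa_loadings is not None
             else np.full(m, np.sqrt(self.var_components.V_L)))
        psi = (self.fa_specific if self.fa_specific is not None
               else np.full(m, self.var_components.V_LxE))
        return np.outer(t, t) + np.diag(psi)

    def line_ids(self) -> list:
        return [f"L{i + 1:04d}" for i in range(self.n_lines)]

    def to_yaml(self, path) -> None:
        d = {k: v for k, v in self.__dict__.items()}
        d["var_components"] = {f: getattr(self.var_components, f)
                               for f in ("V_L", "V_LxE", "V_LT", "V_LTE",
                                         "V_R", "m", "t", "r")}
        for key in ("fa_loadings", "fa_specific"):
            if d[key] is not None:
                d[key] = [float(x) for x in d[key]]
        d["allele_freq_law"] = list(self.allele_freq_law)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


def simulate_marker_matrix(config: SimConfig) -> MarkerMatrix:
    """Bernoulli 0/1 calls at exchangeable loci with drawn allele frequencies.

    The generating frequencies are drawn from the configured law on the
    open interval (0, 1); laws putting mass at 0 or 1 are rejected because
    they create markers that carry no information and break the VanRaden
    denominator in expectation.
    """
    rng = _rng(config, 0)
    law = config.allele_freq_law
    if law[0] == "uniform":
        lo, hi = float(law[1]), float(law[2])
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("uniform allele frequency bounds must satisfy "
                             "0 < lo < hi < 1")
        freqs = rng.uniform(lo, hi, size=config.n_markers)
    elif law[0] == "fixed":
        freqs = np.asarray(law[1], float)
        if len(freqs) != config.n_markers:
            raise ValueError("fixed law needs one frequency per marker")
        if ((freqs < 0.0) | (freqs > 1.0)).any():
            raise ValueError("fixed frequencies must lie in [0, 1]")
    else:
        raise ValueError(f"unknown allele frequency law {law[0]!r}")
    calls = (rng.random((config.n_lines, config.n_markers)) < freqs).astype(float)
    return MarkerMatrix(config.line_ids(),
                        [f"M{j + 1:05d}" for j in range(config.n_markers)],
                        calls)


@dataclass
class TrueGeneticValues:
    """Latent genetic values per line x tester x environment cell."""

    line_ids: list
    testers: list
    environments: list
    u: np.ndarray            # line x env, cov (TT'+Psi) kron G
    tester_eff: np.ndarray   # per tester
    env_tester: np.ndarray   # env x tester
    line_tester: np.ndarray  # line x tester
    lte: np.ndarray          # line x tester x env
    env_cov: np.ndarray      # the TT'+Psi used

    def cell_values(self) -> np.ndarray:
        """Total genetic value, shape (n_lines, n_testers, n_env)."""
        v = (self.u[:, None, :]
             + self.tester_eff[None, :, None]
             + self.env_tester.T[None, :, :]
             + self.line_tester[:, :, None]
             + self.lte)
        return v

    def line_merit(self) -> np.ndarray:
        """True per-line breeding value: mean over testers and environments."""
        return self.cell_values().mean(axis=(1, 2))


def simulate_true_values(G, config: SimConfig) -> TrueGeneticValues:
    """Draw genetic effects with covariance (T T' + Psi) kron G.

    ``G`` may be a GenomicRelationship, a plain symmetric PSD matrix, or
    None for independent lines.  Line-by-environment values U satisfy
    cov(vec U) = Sigma_E kron G via U = G^{1/2} X Sigma_E^{1/2}'.
    """
    if G is None:
        Gm = np.eye(config.n_lines)
    elif isinstance(G, GenomicRelationship):
        Gm = G.G_cond if G.G_cond is not None else G.G
    else:
        Gm = np.asarray(G, float)
    if Gm.shape != (config.n_lines, config.n_lines):
        raise ValueError("G size does not match n_lines")
    w, v = np.linalg.eigh(Gm)
    if w[0] < -1e-8 * max(1.0, w[-1]):
        raise ValueError(f"G is not positive semi-definite "
                         f"(smallest eigenvalue {w[0]:.3e})")
    G_half = v * np.sqrt(np.clip(w, 0.0, None))
    sigma_env = config.env_covariance()
    we, ve = np.linalg.eigh(sigma_env)
    S_half = ve * np.sqrt(np.clip(we, 0.0, None))

    rng = _rng(config, 1)
    n, t, m = config.n_lines, config.n_testers, config.n_environments
    U = G_half @ rng.standard_normal((n, m)) @ S_half.T
    c = config.var_components
    return TrueGeneticValues(
        line_ids=config.line_ids(),
        testers=[f"T{j + 1}" for j in range(t)],
        environments=[f"env{k + 1}" for k in range(m)],
        u=U,
        tester_eff=rng.normal(0.0, np.sqrt(config.tester_var), t),
        env_tester=rng.normal(0.0, np.sqrt(config.env_tester_var), (m, t)),
        line_tester=rng.normal(0.0, np.sqrt(c.V_LT), (n, t)),
        lte=rng.normal(0.0, np.sqrt(c.V_LTE), (n, t, m)),
        env_cov=sigma_env)


def simulate_trial(true_values: TrueGeneticValues,
                   config: SimConfig) -> pd.DataFrame:
    """Plot-level phenotype records for a complete replicated trial.

    Lines are partitioned once into experiments (the same partition in
    every environment, so each line sits in exactly one experiment), each
    experiment is replicated, and plots within a replicate are grouped into
    blocks.  value = mu + design effects + block + genetic value + residual.
    """
    c = config.var_components
    h2 = heritability(c)  # validates the component set
    if not (0.0 < h2 <= 1.0):  # pragma: no cover - heritability() guarantees
        raise ValueError("target heritability outside (0, 1]")
    rng = _rng(config, 2)
    n, t, m = config.n_lines, config.n_testers, config.n_environments
    n_exp, n_rep, n_blk = (config.n_experiments_per_env, config.n_reps,
                           config.blocks_per_rep)
    sd = config.design_effect_sd
    env_eff = rng.normal(0.0, sd, m)
    exp_eff = rng.normal(0.0, sd, n_exp)
    env_exp_eff = rng.normal(0.0, sd, (m, n_exp))
    rep_eff = rng.normal(0.0, sd, (m, n_exp, n_rep))

    # even partition of lines into experiments, fixed across environments
    bounds = np.linspace(0, n, n_exp + 1).astype(int)
    exp_of_line = np.empty(n, dtype=int)
    for e in range(n_exp):
        exp_of_line[bounds[e]:bounds[e + 1]] = e

    cells = true_values.cell_values()
    rows = []
    for k in range(m):
        for e in range(n_exp):
            members = np.flatnonzero(exp_of_line == e)
            for r in range(n_rep):
                block_eff = rng.normal(0.0, np.sqrt(config.block_var), n_blk)
                plots = [(i, j) for i in members for j in range(t)]
                order = rng.permutation(len(plots))
                for pos, idx in enumerate(order):
                    i, j = plots[idx]
                    b = pos * n_blk // len(plots)
                    value = (config.mu + env_eff[k] + exp_eff[e]
                             + env_exp_eff[k, e] + rep_eff[k, e, r]
                             + block_eff[b] + cells[i, j, k]
                             + rng.normal(0.0, np.sqrt(c.V_R)))
                    rows.append((true_values.environments[k], f"exp{e + 1}",
                                 f"rep{r + 1}", f"blk{b + 1:02d}",
                                 true_values.line_ids[i],
                                 true_values.testers[j], value))
    return pd.DataFrame(rows, columns=["env", "experiment", "rep", "block",
                                       "line", "tester", "value"])


def write_phenotypes(pheno: pd.DataFrame, path, seed: int | None = None) -> None:
    """Tidy phenotype CSV; the generating seed is recorded in a header line."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        pheno.to_csv(fh, index=False)
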