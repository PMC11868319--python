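"""Orchestration: design x simulation x trait evaluation and AM-RM correlation.

For each sparse design and simulation index, lines are randomly allocated to
full/sparse sets, the corresponding cells are masked, the genomic prediction
model is refit (or re-solved at the complete-data variance components), and
one evaluation record is produced: the eight training/testing relationship
measures of the allocation plus the four accuracy measures of the resulting
predictions.  Across simulations within a (design, trait) cell, each
accuracy measure is correlated with each relationship measure (Pearson r,
two-sided t-test p-value, significance at 0.05) to ask whether the
relationship between the full and sparse sets predicts how well a random
allocation will perform.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__ as _pkg_version
from .accuracy import AM_NAMES, compute_all_ams
from .adjust import adjusted_values, fit_adjustment_model
from .designs import (SparseDesignSpec, allocate_lines, builtin_designs,
                      mask_phenotypes)
from .gblup import breeding_values, fit_gblup, plugin_params
from .grm import (condition_and_invert, distance_matrix, filter_markers,
                  pca_scores, vanraden_g)
from .relationship import RM_NAMES, compute_all_rms
from .simulate import (SimConfig, simulate_marker_matrix, simulate_trial,
                       simulate_true_values)

__all__ = [
    "ExperimentConfig",
    "enumerate_run_specs",
    "run_design",
    "am_rm_correlations",
    "run_experiment",
    "plot_correlation_heatmap",
]

log = logging.getLogger("sparsemet")

RECORD_COLUMNS = (("design_id", "simulation", "trait", "seed")
                  + RM_NAMES + AM_NAMES)


def _design_code(design_id: str) -> int:
    return zlib.crc32(design_id.encode()) & 0xFFFF


def _child_seed(base_seed: int, *key) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(base_seed), *[int(k) for k in key]])


def enumerate_run_specs(designs=None, n_sims: int = 100,
                        traits=("GY", "EPP", "PH", "EH")) -> list:
    """The (design, simulation, trait) grid, one entry per model run."""
    if designs is None:
        designs = builtin_designs()
    return [(spec.design_id, s, trait)
            for trait in traits for spec in designs for s in range(n_sims)]


def run_design(adjusted: pd.DataFrame, g, P, Dst, spec: SparseDesignSpec,
               n_sims: int, base_seed: int, complete_fit=None,
               mode: str = "FA1", lam: float = 1e-5,
               reestimate: bool = False, top_fraction: float = 0.10,
               trait: str = "trait", tol: float = 1e-6,
               max_iter: int = 1000) -> pd.DataFrame:
    """Evaluate one design over seeded random allocations.

    The complete-data fit (source of the observed breeding values and, in
    plug-in mode, of the variance components for every masked solve) is
    computed once if not supplied.  Per-simulation failures are logged and
    re-raised only if more than 10% of the simulations fail.
    """
    if n_sims < 2:
        raise ValueError("need at least 2 simulations per design")
    line_ids = list(g.line_ids)
    if len(line_ids) != spec.n_lines:
        raise ValueError(f"design expects {spec.n_lines} lines, "
                         f"G has {len(line_ids)}")
    if complete_fit is None:
        complete_fit = fit_gblup(adjusted, g, mode=mode, tol=tol,
                                 max_iter=max_iter,
                                 require_convergence=False)
    params = None if reestimate else plugin_params(complete_fit)
    dcode = _design_code(spec.design_id)
    rows, failures = [], []
    for s in range(n_sims):
        ss = _child_seed(base_seed, dcode, s)
        try:
            alloc = allocate_lines(spec, line_ids, ss)
            masked, _ = mask_phenotypes(adjusted, alloc)
            masked_fit = fit_gblup(masked, g, mode=mode, tol=tol,
                                   max_iter=max_iter, params=params,
                                   require_convergence=False)
            bv = breeding_values(complete_fit, masked_fit)
            am = compute_all_ams(bv, top_fraction=top_fraction)
            rm = compute_all_rms(P, Dst, alloc, lam=lam)
        except Exception as exc:
            failures.append((s, repr(exc)))
            log.warning("design %s simulation %d failed: %r",
                        spec.design_id, s, exc)
            continue
        rows.append({"design_id": spec.design_id, "simulation": s,
                     "trait": trait, "seed": f"{base_seed}/{dcode}/{s}",
                     **rm.as_dict(), **am.as_dict()})
    if len(failures) > 0.10 * n_sims:
        raise RuntimeError(
            f"design {spec.design_id}: {len(failures)}/{n_sims} simulations "
            f"failed; first failures: {failures[:3]}")
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def am_rm_correlations(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between each AM and RM across simulations per (design, trait).

    p-values come from the t-statistic with n-2 degrees of freedom
    (two-sided); pairs where either metric is constant across simulations
    are reported with undefined (NaN) r and excluded from significance.
    A Benjamini-Hochberg adjusted p-value within each (design, trait) cell
    is emitted alongside the raw significance flag.
    """
    from statsmodels.stats.multitest import multipletests

    out = []
    for (design, trait), grp in records.groupby(["design_id", "trait"]):
        n = len(grp)
        if n < 3:
            raise ValueError(f"need >= 3 records per cell, got {n} for "
                             f"({design}, {trait})")
        cell = []
        for am in AM_NAMES:
            for rm in RM_NAMES:
                x = grp[rm].to_numpy(float)
                yv = grp[am].to_numpy(float)
                if np.ptp(x) == 0 or np.ptp(yv) == 0:
                    cell.append((design, trait, am, rm, n,
                                 np.nan, np.nan, False))
                    continue
                r, p = stats.pearsonr(x, yv)
                cell.append((design, trait, am, rm, n, float(r), float(p),
                             bool(p < 0.05)))
        df = pd.DataFrame(cell, columns=["design_id", "trait", "AM", "RM",
                                         "n", "r", "p", "significant"])
        ok = df["p"].notna()
        df["p_bh"] = np.nan
        if ok.any():
            df.loc[ok, "p_bh"] = multipletests(df.loc[ok, "p"],
                                               method="fdr_bh")[1]
        out.append(df)
    return pd.concat(out, ignore_index=True)


@dataclass
class ExperimentConfig:
    """End-to-end study configuration (synthetic generation to correlations)."""

    traits: tuple = ("GY",)
    designs: list | None = None       # None -> the 14 built-in designs
    n_sims: int = 100
    base_seed: int = 20180501
    sim: SimConfig | None = None      # dimension/noise template
    mode: str = "FA1"
    lam: float = 1e-5
    reestimate: bool = False
    top_fraction: float = 0.10
    maf_bounds: tuple = (0.05, 0.95)
    blend_weight: float = 0.02
    gblup_tol: float = 1e-6
    gblup_max_iter: int = 1000
    adjust_tol: float = 1e-6
    adjust_max_iter: int = 200
    outdir: str | None = None
    make_figures: bool = False

    def resolved_designs(self) -> list:
        designs = self.designs if self.designs is not None else builtin_designs()
        return [d if isinstance(d, SparseDesignSpec) else
                next(s for s in builtin_designs() if s.design_id == d)
                for d in designs]


@dataclass
class ExperimentResult:
    records: pd.DataFrame
    correlations: pd.DataFrame
    paths: dict = field(default_factory=dict)


def _trait_pipeline(cfg: ExperimentConfig, trait: str, trait_idx: int):
    """Synthetic data -> G machinery -> adjusted values, for one trait."""
    template = cfg.sim if cfg.sim is not None else SimConfig()
    seed = int(_child_seed(cfg.base_seed, 1, trait_idx).generate_state(1)[0]
               % (2 ** 31))
    sim_kwargs = {k: v for k, v in template.__dict__.items()
                  if k not in ("var_components", "seed")}
    sim_cfg = SimConfig.for_trait(trait, seed=seed, **sim_kwargs)
    markers = simulate_marker_matrix(sim_cfg)
    kept, _ = filter_markers(markers, *cfg.maf_bounds)
    g = condition_and_invert(vanraden_g(kept), cfg.blend_weight)
    P = pca_scores(g)
    Dst = distance_matrix(kept)
    truth = simulate_true_values(g, sim_cfg)
    pheno = simulate_trial(truth, sim_cfg)
    fit = fit_adjustment_model(pheno, tol=cfg.adjust_tol,
                               max_iter=cfg.adjust_max_iter,
                               require_convergence=False)
    adjusted = adjusted_values(fit, pheno)
    return sim_cfg, g, P, Dst, adjusted, truth


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """The full study: simulate, allocate, mask, predict, score, correlate.

    Deterministic for a fixed configuration: rerunning writes byte-identical
    tables.  Outputs (records.csv, correlations.csv, manifest.yaml and an
    optional heatmap per accuracy measure) go to cfg.outdir when set.
    """
    designs = cfg.resolved_designs()
    all_records = []
    for trait_idx, trait in enumerate(cfg.traits):
        log.info("trait %s: generating synthetic trial", trait)
        sim_cfg, g, P, Dst, adjusted, _ = _trait_pipeline(cfg, trait, trait_idx)
        for spec in designs:
            if spec.n_lines != sim_cfg.n_lines:
                raise ValueError(
                    f"design {spec.design_id} is for {spec.n_lines} lines "
                    f"but the simulation has {sim_cfg.n_lines}")
        complete_fit = fit_gblup(adjusted, g, mode=cfg.mode,
                                 tol=cfg.gblup_tol,
                                 max_iter=cfg.gblup_max_iter,
                                 require_convergence=False)
        for spec in designs:
            log.info("trait %s design %s: %d simulations",
                     trait, spec.design_id, cfg.n_sims)
            rec = run_design(adjusted, g, P, Dst, spec, cfg.n_sims,
                             cfg.base_seed, complete_fit=complete_fit,
                             mode=cfg.mode, lam=cfg.lam,
                             reestimate=cfg.reestimate,
                             top_fraction=cfg.top_fraction, trait=trait,
                             tol=cfg.gblup_tol, max_iter=cfg.gblup_max_iter)
            all_records.append(rec)
    records = pd.concat(all_records, ignore_index=True)
    correlations = am_rm_correlations(records)
    result = ExperimentResult(records, correlations)
    if cfg.outdir is not None:
        _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: ExperimentConfig, result: ExperimentResult) -> None:
    import os

    os.makedirs(cfg.outdir, exist_ok=True)
    written = []
    try:
        rec_path = os.path.join(cfg.outdir, "records.csv")
        result.records.to_csv(rec_path, index=False, float_format="%.10g")
        written.append(rec_path)
        cor_path = os.path.join(cfg.outdir, "correlations.csv")
        result.correlations.to_csv(cor_path, index=False,
                                   float_format="%.10g")
        written.append(cor_path)
        man_path = os.path.join(cfg.outdir, "manifest.yaml")
        manifest = {
            "package": "sparsemet",
            "version": _pkg_version,
            "base_seed": cfg.base_seed,
            "n_sims": cfg.n_sims,
            "traits": list(cfg.traits),
            "designs": [d.design_id for d in cfg.resolved_designs()],
            "mode": cfg.mode,
            "lambda": cfg.lam,
            "reestimate": cfg.reestimate,
        }
        with open(man_path, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        written.append(man_path)
        if cfg.make_figures:
            fig_path = os.path.join(cfg.outdir, "am_rm_heatmap.png")
            plot_correlation_heatmap(result.correlations, fig_path)
            written.append(fig_path)
    except Exception:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise
    result.paths = {os.path.basename(p): p for p in written}


def plot_correlation_heatmap(correlations: pd.DataFrame, path) -> None:
    """Design x RM heatmap per AM; cells colored only when p < 0.05."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traits = sorted(correlations["trait"].unique())
    designs = list(dict.fromkeys(correlations["design_id"]))
    fig, axes = plt.subplots(len(AM_NAMES), len(traits), squeeze=False,
                             figsize=(4 * len(traits), 3 * len(AM_NAMES)))
    for ai, am in enumerate(AM_NAMES):
        for ti, trait in enumerate(traits):
            sub = correlations[(correlations["AM"] == am)
                               & (correlations["trait"] == trait)]
            grid = np.full((len(designs), len(RM_NAMES)), np.nan)
            for _, row in sub.iterrows():
                if row["significant"]:
                    di = designs.index(row["design_id"])
                    ri = RM_NAMES.index(row["RM"])
                    grid[di, ri] = row["r"]
            ax = axes[ai][ti]
            im = ax.imshow(grid, vmin=-1, vmax=1, cmap="RdBu_r",
                           aspect="auto")
            ax.set_xticks(range(len(RM_NAMES)), RM_NAMES, rotation=90,
                          fontsize=7)
            ax.set_yticks(range(len(designs)), designs, fontsize=7)
            ax.set_title(f"{am} / {trait}", fontsize=9)
    fig.colorbar(im, ax=[a for row in axes for a in row], shrink=0.6)
    fig.savefig(path, dpi=120)
    plt.close(fig)
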