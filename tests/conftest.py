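import numpy as np
import pytest

import sparsemet as sm


@pytest.fixture(scope="session")
def small_pipeline():
    """One small but complete synthetic trial shared across test modules.

    40 lines x 2 testers x 5 environments, marker-derived G, adjusted
    values and a converged complete-data GBLUP fit.
    """
    cfg = sm.SimConfig(n_lines=40, n_testers=2, n_environments=5,
                       n_experiments_per_env=1, n_reps=2, blocks_per_rep=4,
                       n_markers=400, seed=7)
    markers = sm.simulate_marker_matrix(cfg)
    kept, _ = sm.filter_markers(markers)
    g = sm.condition_and_invert(sm.vanraden_g(kept))
    P = sm.pca_scores(g)
    Dst = sm.distance_matrix(kept)
    truth = sm.simulate_true_values(g, cfg)
    pheno = sm.simulate_trial(truth, cfg)
    fit = sm.fit_adjustment_model(pheno, max_iter=100,
                                  require_convergence=False)
    adjusted = sm.adjusted_values(fit, pheno)
    complete = sm.fit_gblup(adjusted, g, max_iter=300, tol=1e-6,
                            require_convergence=False)
    return {"cfg": cfg, "markers": kept, "g": g, "P": P, "Dst": Dst,
            "truth": truth, "pheno": pheno, "adjust_fit": fit,
            "adjusted": adjusted, "complete_fit": complete}


@pytest.fixture(scope="session")
def ladder_study():
    """Sparse-design ladder on synthetic data at reduced population size.

    150 lines, 5 environments, 3 testers, grain-yield heritability preset
    (0.75); two full-set fractions (50 and 75 of 150 lines) each evaluated
    at 4, 3, 2, 1 and 0 tested environments per sparse set, 20 seeded
    allocations per design, plug-in variance components from the
    complete-data fit.
    """
    cfg = sm.SimConfig(n_lines=150, n_testers=3, n_environments=5,
                       n_experiments_per_env=1, n_reps=2, blocks_per_rep=10,
                       n_markers=1000, seed=20180501)
    markers, _ = sm.filter_markers(sm.simulate_marker_matrix(cfg))
    g = sm.condition_and_invert(sm.vanraden_g(markers))
    P = sm.pca_scores(g)
    Dst = sm.distance_matrix(markers)
    truth = sm.simulate_true_values(g, cfg)
    pheno = sm.simulate_trial(truth, cfg)
    fit = sm.fit_adjustment_model(pheno, max_iter=20,
                                  require_convergence=False)
    adjusted = sm.adjusted_values(fit, pheno)
    complete = sm.fit_gblup(adjusted, g, max_iter=300, tol=1e-5,
                            require_convergence=False)
    records = {}
    for n_full, tag in ((50, "F50"), (75, "F75")):
        for tested in (4, 3, 2, 1, 0):
            spec = sm.SparseDesignSpec(
                design_id=f"{tag}T{tested}", n_full=n_full,
                n_sparse_sets=1 if tested == 0 else 5,
                n_tested_env_per_ss=tested, balanced=True, n_lines=150)
            records[(tag, tested)] = sm.run_design(
                adjusted, g, P, Dst, spec, n_sims=20, base_seed=97,
                complete_fit=complete)
    return {"records": records, "complete_fit": complete, "g": g,
            "adjusted": adjusted, "P": P, "Dst": Dst, "truth": truth}
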