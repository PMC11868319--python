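import numpy as np
import pandas as pd
import pytest

import sparsemet as sm
from sparsemet.gblup import breeding_values, fit_gblup, plugin_params
from sparsemet.grm import GenomicRelationship, condition_and_invert
from helpers import assert_monotone_loglik


def _grid_df(values, line_ids, testers, envs):
    rows = []
    for i, l in enumerate(line_ids):
        for j, t in enumerate(testers):
            for k, e in enumerate(envs):
                rows.append((l, t, e, values[i, j, k]))
    return pd.DataFrame(rows, columns=["line", "tester", "env", "value"])


def _identity_g(n):
    return condition_and_invert(
        GenomicRelationship([f"L{i:03d}" for i in range(n)], np.eye(n)), 0.0)


class TestFitGblup:
    def test_interpolates_when_noise_free(self):
        # complete data generated without any cell-level noise: the fitted
        # cells reproduce the inputs almost exactly
        n, t, m = 30, 2, 4
        rng = np.random.default_rng(17)
        g = _identity_g(n)
        u_le = rng.standard_normal((n, m))
        lt = 0.6 * rng.standard_normal((n, t))
        tau = 0.5 * rng.standard_normal(t)
        env = rng.standard_normal(m)
        vals = (env[None, None, :] + tau[None, :, None]
                + lt[:, :, None] + u_le[:, None, :])
        df = _grid_df(vals, g.line_ids, [f"T{j+1}" for j in range(t)],
                      [f"env{k+1}" for k in range(m)])
        fit = fit_gblup(df, g, mode="FA1", tol=1e-8, max_iter=600,
                        require_convergence=False)
        pred = fit.cell_predictions().set_index(["line", "tester", "env"])
        obs = df.set_index(["line", "tester", "env"])
        joined = pred.join(obs, lsuffix="_hat")
        r = np.corrcoef(joined["value_hat"], joined["value"])[0, 1]
        assert r > 0.999

    def test_ridge_equivalence_single_environment(self):
        # one env, one tester: GBLUP at fixed variances equals ridge on the
        # PCA scores with lambda = s2e/s2g (intercept unpenalized)
        rng = np.random.default_rng(21)
        n, k = 25, 25
        scores = rng.standard_normal((n, k))
        G = scores @ scores.T / k + 0.3 * np.eye(n)
        g = condition_and_invert(
            GenomicRelationship([f"L{i:03d}" for i in range(n)], G), 0.0)
        y = rng.standard_normal(n) + 4.0
        df = _grid_df(y.reshape(n, 1, 1), g.line_ids, ["T1"], ["env1"])
        s2g, s2e = 1.4, 0.7
        params = {"tester": 1e-8, "env:tester": 1e-8, "line:tester": 1e-8,
                  "line": s2g, "line:env": 1e-8, "sigma2_e": s2e}
        fit = fit_gblup(df, g, mode="RN", params=params)
        lam = s2e / s2g
        V = s2g * g.G_cond + s2e * np.eye(n)
        Vi = np.linalg.inv(V)
        ones = np.ones(n)
        b = (ones @ Vi @ y) / (ones @ Vi @ ones)
        u_ref = s2g * g.G_cond @ Vi @ (y - b)
        np.testing.assert_allclose(fit.result.u["line"], u_ref, atol=1e-5)

    def test_fa1_recovers_env_covariance(self):
        # data simulated from a known one-factor covariance: the estimated
        # Sigma_E tracks the truth elementwise across replicates
        n, m = 80, 4
        loadings = np.array([1.2, 1.0, 0.8, 1.1])
        psi = np.array([0.4, 0.7, 0.3, 0.5])
        sigma_true = np.outer(loadings, loadings) + np.diag(psi)
        g = _identity_g(n)
        cors = []
        for rep in range(6):
            rng = np.random.default_rng(500 + rep)
            B = np.linalg.cholesky(sigma_true)
            U = rng.standard_normal((n, m)) @ B.T
            noise = 0.5 * rng.standard_normal((n, m))
            df = _grid_df((U + noise)[:, None, :], g.line_ids, ["T1"],
                          [f"env{k+1}" for k in range(m)])
            fit = fit_gblup(df, g, mode="FA1", tol=1e-7, max_iter=500,
                            require_convergence=False)
            est = fit.fa.sigma_env()
            cors.append(np.corrcoef(est.ravel(), sigma_true.ravel())[0, 1])
        assert np.mean(cors) > 0.9

    def test_loglik_monotone(self, small_pipeline):
        fit = small_pipeline["complete_fit"]
        assert_monotone_loglik(fit.result.loglik_trace)

    def test_record_order_invariance(self, small_pipeline):
        adj = small_pipeline["adjusted"]
        g = small_pipeline["g"]
        params = plugin_params(small_pipeline["complete_fit"])
        f1 = fit_gblup(adj, g, params=params)
        shuffled = adj.sample(frac=1.0, random_state=3).reset_index(drop=True)
        f2 = fit_gblup(shuffled, g, params=params)
        np.testing.assert_allclose(f1.line_env, f2.line_env, atol=1e-8)
        np.testing.assert_allclose(f1.line_values(), f2.line_values(),
                                   atol=1e-8)

    def test_empty_and_unconditioned_inputs_rejected(self, small_pipeline):
        g = small_pipeline["g"]
        adj = small_pipeline["adjusted"]
        with pytest.raises(ValueError, match="no records"):
            fit_gblup(adj.iloc[:0], g)
        raw = GenomicRelationship(list(g.line_ids), g.G)
        with pytest.raises(ValueError, match="conditioned"):
            fit_gblup(adj, raw)


class TestModes:
    def test_rn_is_special_case_of_fa1(self):
        # data generated under compound symmetry: both modes produce nearly
        # the same per-line predictions
        n, m = 50, 4
        g = _identity_g(n)
        rng = np.random.default_rng(31)
        main = 1.3 * rng.standard_normal(n)
        inter = 0.7 * rng.standard_normal((n, m))
        y = main[:, None] + inter + 0.4 * rng.standard_normal((n, m))
        df = _grid_df(y[:, None, :], g.line_ids, ["T1"],
                      [f"env{k+1}" for k in range(m)])
        fa = fit_gblup(df, g, mode="FA1", tol=1e-7, max_iter=800,
                       require_convergence=False)
        rn = fit_gblup(df, g, mode="RN", tol=1e-7, max_iter=800,
                       require_convergence=False)
        r = np.corrcoef(fa.line_values(), rn.line_values())[0, 1]
        assert r > 0.99


class TestBreedingValues:
    def test_identical_fits_give_unit_correlation(self, small_pipeline):
        cf = small_pipeline["complete_fit"]
        bv = breeding_values(cf, cf)
        np.testing.assert_array_equal(bv.obv, bv.pbv)
        assert sm.pearson_accuracy(bv) == pytest.approx(1.0)

    def test_untested_lines_predicted_through_g_only(self):
        # permuting the G-rows of fully-masked lines permutes their
        # predictions identically: information flows only through G
        n, m = 30, 3
        rng = np.random.default_rng(41)
        A = rng.standard_normal((n, 60))
        G = A @ A.T / 60
        ids = [f"L{i:03d}" for i in range(n)]
        g = condition_and_invert(GenomicRelationship(ids, G), 0.02)
        y = rng.standard_normal((n, 1, m)) + 2.0
        df = _grid_df(y, ids, ["T1"], [f"env{k+1}" for k in range(m)])
        tested = df[df["line"] < "L020"]  # L020..L029 fully masked
        fit = fit_gblup(tested, g, mode="FA1", max_iter=300,
                        require_convergence=False)
        # permute the masked block of G and refit
        perm = np.arange(n)
        perm[20:] = 20 + np.roll(np.arange(10), 3)
        Gp = G[np.ix_(perm, perm)]
        gp = condition_and_invert(GenomicRelationship(ids, Gp), 0.02)
        fit_p = fit_gblup(tested, gp, mode="FA1", max_iter=300,
                          require_convergence=False)
        np.testing.assert_allclose(fit_p.line_values()[20:],
                                   fit.line_values()[perm[20:]], atol=1e-6)

    def test_line_set_mismatch_rejected(self, small_pipeline):
        cf = small_pipeline["complete_fit"]
        other = fit_gblup(
            small_pipeline["adjusted"][lambda d: d.line != cf.line_ids[0]],
            _clone_without(small_pipeline["g"], cf.line_ids[0]),
            params=None, max_iter=30, require_convergence=False)
        with pytest.raises(ValueError, match="different line sets"):
            breeding_values(cf, other)


def _clone_without(g, line):
    keep = [i for i, l in enumerate(g.line_ids) if l != line]
    sub = GenomicRelationship([g.line_ids[i] for i in keep],
                              g.G[np.ix_(keep, keep)])
    return condition_and_invert(sub, 0.02)
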