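import numpy as np
import pytest

from sparsemet.designs import SparseDesignSpec, allocate_lines
from sparsemet.relationship import (RM_NAMES, compute_all_rms, pev_matrix,
                                    rm_aopt_goptpev, rm_cd, rm_neg_dist,
                                    rm_pev_summaries)

from helpers import naive_rms

LAM = 1e-5


def _scores(n, k, seed=0):
    return np.random.default_rng(seed).standard_normal((n, k))


class TestPevMatrix:
    def test_orthogonal_test_row_blows_up(self):
        # test direction unseen in training: PEV_ii -> p'p / lambda
        P = np.eye(3) * 2.0
        pev = pev_matrix(P[:2], P[2:], LAM)
        assert pev[0, 0] == pytest.approx(4.0 / LAM, rel=1e-10)

    def test_matches_naive(self):
        P = _scores(10, 4, seed=1)
        pev = pev_matrix(P[:6], P[6:], 0.01)
        ref = naive_rms(P, np.zeros((10, 10)), range(6), range(6, 10), 0.01)
        A = P[:6].T @ P[:6] + 0.01 * np.eye(4)
        np.testing.assert_allclose(pev, P[6:] @ np.linalg.inv(A) @ P[6:].T,
                                   atol=1e-10)
        assert np.diag(pev).mean() == pytest.approx(ref["PEVMEAN"])

    def test_duplicating_training_line_shrinks_pev(self):
        P = _scores(8, 3, seed=2)
        pev1 = pev_matrix(P[:5], P[5:], LAM)
        pev2 = pev_matrix(np.vstack([P[:5], P[0]]), P[5:], LAM)
        assert (np.diag(pev2) <= np.diag(pev1) + 1e-12).all()

    def test_empty_sets_rejected(self):
        P = _scores(4, 2)
        with pytest.raises(ValueError):
            pev_matrix(P[:0], P[2:], LAM)
        with pytest.raises(ValueError):
            pev_matrix(P[:2], P[2:], 0.0)


class TestSummaries:
    def test_single_test_line_degenerate(self):
        P = _scores(6, 3, seed=3)
        pm, px, dopt = rm_pev_summaries(P[:5], P[5:], LAM)
        assert pm == px
        pev = pev_matrix(P[:5], P[5:], LAM)
        assert dopt == pytest.approx(np.log(pev[0, 0] + 1e-12))
        _, gopt = rm_aopt_goptpev(P[:5], P[5:], LAM)
        assert gopt == pytest.approx(pev[0, 0])

    def test_aopt_orthonormal_closed_form(self):
        lam = 0.3
        P_T = np.eye(4)  # P_T'P_T = I, k columns
        aopt, _ = rm_aopt_goptpev(P_T, _scores(2, 4), lam)
        assert aopt == pytest.approx(4 / (1 + lam), rel=1e-12)

    def test_training_monotonicity(self):
        # adding training lines never hurts any PEV/CD criterion
        rng = np.random.default_rng(4)
        P = rng.standard_normal((20, 6))
        test = P[15:]
        for _ in range(10):
            size = rng.integers(3, 12)
            idx = rng.choice(15, size=size, replace=False)
            bigger = np.append(idx, [i for i in range(15) if i not in idx][:3])
            pm1, px1, _ = rm_pev_summaries(P[idx], test, LAM)
            pm2, px2, _ = rm_pev_summaries(P[bigger], test, LAM)
            assert pm2 <= pm1 + 1e-9 and px2 <= px1 + 1e-9
            cdm1, cdx1 = rm_cd(P[idx], test, LAM)
            cdm2, cdx2 = rm_cd(P[bigger], test, LAM)
            assert cdm2 >= cdm1 - 1e-9 and cdx2 >= cdx1 - 1e-9
            _, g1 = rm_aopt_goptpev(P[idx], test, LAM)
            _, g2 = rm_aopt_goptpev(P[bigger], test, LAM)
            assert g2 <= g1 + 1e-9

    def test_exact_rescaling(self):
        # rescaling the scores by c with lambda rescaled by c^2 leaves the
        # PEV matrix unchanged, and hence every CD unchanged
        P = _scores(9, 4, seed=5)
        c = 3.7
        pev = pev_matrix(P[:6], P[6:], LAM)
        pev_c = pev_matrix(c * P[:6], c * P[6:], c ** 2 * LAM)
        np.testing.assert_allclose(pev_c, pev, rtol=1e-10)
        np.testing.assert_allclose(rm_cd(c * P[:6], c * P[6:], c ** 2 * LAM),
                                   rm_cd(P[:6], P[6:], LAM), rtol=1e-9)


class TestCd:
    def test_copy_of_training_line_fully_reliable(self):
        P = _scores(6, 4, seed=6)
        cdm, cdx = rm_cd(P[:5], P[0:1], 1e-10)
        assert cdx == pytest.approx(1.0, abs=1e-6)

    def test_orthogonal_test_line_unreliable(self):
        P = np.eye(3) * 2.0
        cdm, _ = rm_cd(P[:2], P[2:], LAM)
        assert cdm == pytest.approx(LAM / (4.0 + LAM), rel=1e-6)

    def test_cd_in_unit_interval(self):
        for seed in range(5):
            P = _scores(15, 5, seed=seed)
            cdm, cdx = rm_cd(P[:9], P[9:], LAM)
            assert 0.0 <= cdm <= cdx <= 1.0


class TestNegDist:
    def test_identical_clusters(self):
        D = np.zeros((4, 4))
        assert rm_neg_dist(D, [0, 1], [2, 3]) == 0.0

    def test_two_separated_clusters(self):
        # train in one cluster, test in the other, inter-distance d
        d = 2.5
        D = np.zeros((4, 4))
        D[:2, 2:] = d
        D[2:, :2] = d
        assert rm_neg_dist(D, [0, 1], [2, 3]) == pytest.approx(-d)

    def test_moving_test_line_closer_increases_ndt(self):
        D = np.zeros((4, 4))
        D[:2, 2:] = [[3.0, 1.0], [3.0, 1.0]]
        D[2:, :2] = D[:2, 2:].T
        far = rm_neg_dist(D, [0, 1], [2])
        near = rm_neg_dist(D, [0, 1], [3])
        assert near > far


class TestComputeAllRms:
    def _alloc(self, n_lines=30, n_full=10, tested=4, n_sets=5, seed=0):
        spec = SparseDesignSpec("T", n_full=n_full, n_sparse_sets=n_sets,
                                n_tested_env_per_ss=tested, balanced=True,
                                n_lines=n_lines)
        return allocate_lines(spec, [f"L{i:03d}" for i in range(n_lines)],
                              seed)

    def test_matches_reference_script(self):
        rng = np.random.default_rng(7)
        P = rng.standard_normal((30, 30))
        D = np.abs(rng.standard_normal((30, 30)))
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0.0)
        ids = [f"L{i:03d}" for i in range(30)]
        alloc = self._alloc(seed=1)
        rm = compute_all_rms((P, ids), D, alloc, lam=LAM)
        pos = {l: i for i, l in enumerate(ids)}
        ref = naive_rms(P, D, [pos[l] for l in alloc.full_set],
                        [pos[l] for l in alloc.sparse_lines], LAM)
        for name in RM_NAMES:
            assert getattr(rm, name) == pytest.approx(ref[name], rel=1e-10,
                                                      abs=1e-10), name

    def test_depends_only_on_line_partition(self):
        # same split, different environment masking -> identical RM vector
        rng = np.random.default_rng(8)
        P = rng.standard_normal((30, 30))
        D = np.zeros((30, 30))
        a1 = self._alloc(tested=4, n_sets=5, seed=3)
        a2 = self._alloc(tested=0, n_sets=1, seed=3)
        # force the same line partition
        a2.full_set = a1.full_set
        a2.sparse_sets = [sorted(a1.sparse_lines)]
        ids = [f"L{i:03d}" for i in range(30)]
        r1 = compute_all_rms((P, ids), D, a1, lam=LAM)
        r2 = compute_all_rms((P, ids), D, a2, lam=LAM)
        for name in RM_NAMES:
            assert getattr(r1, name) == pytest.approx(getattr(r2, name))

    def test_invariant_to_relabeling(self):
        rng = np.random.default_rng(9)
        P = rng.standard_normal((30, 6))
        D = np.abs(rng.standard_normal((30, 30)))
        np.fill_diagonal(D, 0.0)
        D = 0.5 * (D + D.T)
        ids = [f"L{i:03d}" for i in range(30)]
        alloc = self._alloc(seed=5)
        r1 = compute_all_rms((P, ids), D, alloc, lam=LAM)
        # relabel lines (permute storage order consistently)
        perm = rng.permutation(30)
        ids_p = [ids[i] for i in perm]
        r2 = compute_all_rms((P[perm], ids_p), D[np.ix_(perm, perm)],
                             alloc, lam=LAM)
        for name in RM_NAMES:
            assert getattr(r1, name) == pytest.approx(getattr(r2, name),
                                                      rel=1e-9), name

    def test_invariant_ordering_of_vector(self):
        rng = np.random.default_rng(10)
        P = rng.standard_normal((30, 6))
        D = np.abs(rng.standard_normal((30, 30)))
        np.fill_diagonal(D, 0.0)
        alloc = self._alloc(seed=6)
        rm = compute_all_rms((P, [f"L{i:03d}" for i in range(30)]),
                             0.5 * (D + D.T), alloc)
        assert rm.PEVMEAN <= rm.PEVMAX
        assert rm.CDMEAN <= rm.CDMAX
        assert 0.0 <= rm.CDMEAN and rm.CDMAX <= 1.0
        assert all(np.isfinite(v) for v in rm.as_dict().values())
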