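"""CCA stack: algebra oracles, restricted permutations, surrogates, helpers."""

import numpy as np
import pytest
from scipy import linalg as sla

from topofc import cca as C


def _cca_oracle_correlations(X, Y):
    """Canonical correlations via the generalised eigenproblem on covariance
    blocks — an independent route from the package's QR+SVD solver."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc
    Syy = Yc.T @ Yc
    Sxy = Xc.T @ Yc
    M = sla.solve(Sxx, Sxy) @ sla.solve(Syy, Sxy.T)
    w = np.sort(np.real(sla.eigvals(M)))[::-1]
    return np.sqrt(np.clip(w, 0, 1))


class TestDeconfound:
    def test_no_confounds_demeans(self, rng):
        X = rng.standard_normal((20, 3)) + 5
        out = C.deconfound(X, None)
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out, X - X.mean(axis=0))

    def test_confound_driven_data_vanishes(self, rng):
        conf = rng.standard_normal((30, 2))
        X = conf @ rng.standard_normal((2, 4)) + 3.0
        np.testing.assert_allclose(C.deconfound(X, conf), 0, atol=1e-8)

    def test_residuals_orthogonal_to_confounds(self, rng):
        conf = rng.standard_normal((40, 3))
        X = rng.standard_normal((40, 5))
        resid = C.deconfound(X, conf)
        np.testing.assert_allclose(resid.T @ conf, 0, atol=1e-8)

    def test_rank_deficient_confounds_raise(self, rng):
        c = rng.standard_normal(20)
        with pytest.raises(ValueError):
            C.deconfound(rng.standard_normal((20, 2)), np.column_stack([c, c]))


class TestSubjectCovariance:
    def test_single_block_matches_plain_covariance(self, rng):
        F = rng.standard_normal((8, 50))
        np.testing.assert_allclose(C.subject_covariance(F), np.cov(F), atol=1e-10)

    def test_duplicated_map_doubles(self, rng):
        B = rng.standard_normal((6, 40))
        np.testing.assert_allclose(
            C.subject_covariance([B, B]), 2 * C.subject_covariance([B]), atol=1e-10
        )

    def test_result_symmetric_psd(self, rng):
        cov = C.subject_covariance([rng.standard_normal((10, 30)) for _ in range(3)])
        np.testing.assert_allclose(cov, cov.T, atol=1e-10)
        assert np.linalg.eigvalsh(cov).min() > -1e-8


class TestPairwiseCovarianceMissing:
    def test_no_missingness_equals_plain(self, rng):
        F = rng.standard_normal((6, 25))
        mask = np.zeros_like(F, dtype=bool)
        np.testing.assert_allclose(
            C.pairwise_covariance_missing(F, mask), C.subject_covariance(F), atol=1e-10
        )

    def test_indefinite_case_flagged_and_repaired(self, rng):
        F = rng.standard_normal((12, 8))
        mask = rng.random(F.shape) < 0.4
        mask[:, :2] = False  # every pair shares at least 2 features
        cov = C.pairwise_covariance_missing(F, mask)
        # pairwise-complete estimates are generally indefinite at this scale
        repaired = C.nearest_spd(cov)
        assert np.linalg.eigvalsh(repaired).min() > 0

    def test_insufficient_overlap_raises(self):
        F = np.random.default_rng(0).standard_normal((3, 4))
        mask = np.array(
            [[False, False, True, True], [True, True, False, False], [False, False, False, False]]
        )
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            C.pairwise_covariance_missing(F, mask)


class TestNearestSPD:
    def test_spd_input_unchanged(self, rng):
        A = rng.standard_normal((5, 8))
        S = A @ A.T + 5 * np.eye(5)
        np.testing.assert_allclose(C.nearest_spd(S), S, atol=1e-10)

    def test_indefinite_diagonal_clipped(self):
        out = C.nearest_spd(np.diag([1.0, -1.0]))
        assert out[0, 0] == pytest.approx(1.0)
        assert 0 < out[1, 1] < 1e-8

    def test_min_eigenvalue_floor_and_idempotence(self, rng):
        A = rng.standard_normal((6, 6))
        out = C.nearest_spd(A)
        w = np.linalg.eigvalsh(out)
        assert w.min() > 0
        np.testing.assert_allclose(C.nearest_spd(out), out, atol=1e-9)


class TestSubjectEigenvectors:
    def test_rank_one_recovers_generator(self, rng):
        v = rng.standard_normal(10)
        fm = C.subject_eigenvectors(np.outer(v, v), Kc=3)
        lead = fm.scores[:, 0]
        assert abs(np.corrcoef(lead, v)[0, 1]) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(fm.scores[:, 1:], 0, atol=1e-6)

    def test_score_gram_matches_eigenvalues(self, rng):
        A = rng.standard_normal((12, 30))
        cov = A @ A.T
        fm = C.subject_eigenvectors(cov, Kc=5)
        np.testing.assert_allclose(fm.scores.T @ fm.scores, np.diag(fm.eigenvalues), atol=1e-8)

    def test_sign_convention_stable(self, rng):
        cov = C.nearest_spd(rng.standard_normal((9, 9)))
        a = C.subject_eigenvectors(cov, 4).scores
        b = C.subject_eigenvectors(cov, 4).scores
        np.testing.assert_array_equal(a, b)

    def test_too_many_components_raise(self, rng):
        with pytest.raises(ValueError):
            C.subject_eigenvectors(np.eye(4), Kc=5)


class TestCCAFit:
    def test_self_cca_all_ones(self, rng):
        X = rng.standard_normal((30, 4))
        res = C.cca_fit(X, X.copy())
        np.testing.assert_allclose(res.r, 1.0, atol=1e-10)

    def test_matches_generalised_eigen_oracle(self, rng):
        X = rng.standard_normal((50, 4))
        Y = 0.5 * X @ rng.standard_normal((4, 3)) + rng.standard_normal((50, 3))
        res = C.cca_fit(X, Y)
        np.testing.assert_allclose(res.r, _cca_oracle_correlations(X, Y)[:3], atol=1e-8)

    def test_invariant_to_invertible_remixing(self, rng):
        X = rng.standard_normal((40, 5))
        Y = rng.standard_normal((40, 4))
        A = rng.standard_normal((5, 5)) + 2 * np.eye(5)
        np.testing.assert_allclose(C.cca_fit(X @ A, Y).r, C.cca_fit(X, Y).r, atol=1e-8)

    def test_scores_standardised_and_uncorrelated(self, rng):
        X = rng.standard_normal((60, 5))
        Y = rng.standard_normal((60, 5))
        res = C.cca_fit(X, Y)
        for S in (res.U, res.V):
            np.testing.assert_allclose(np.cov(S, rowvar=False), np.eye(5), atol=1e-8)
        assert (np.diff(res.r) <= 1e-12).all()
        assert res.r.min() >= 0 and res.r.max() <= 1
        # weights reproduce the scores
        np.testing.assert_allclose((X - X.mean(0)) @ res.x_weights, res.U, atol=1e-8)

    def test_one_dimensional_case_equals_plain_correlation(self, rng):
        x = rng.standard_normal((100, 1))
        y = 0.6 * x + 0.8 * rng.standard_normal((100, 1))
        res = C.cca_fit(x, y)
        assert res.r[0] == pytest.approx(abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1]), abs=1e-10)

    def test_too_few_subjects_raise(self, rng):
        with pytest.raises(ValueError):
            C.cca_fit(rng.standard_normal((5, 5)), rng.standard_normal((5, 3)))


class TestRestrictedPermutation:
    def test_families_move_as_units(self, rng):
        family_id = np.repeat(np.arange(6), 3)
        for _ in range(50):
            perm = C.restricted_permutation(family_id, rng)
            # the sources filling each family slot come from exactly one family
            for f in range(6):
                src = family_id[perm[family_id == f]]
                assert len(set(src)) == 1
        assert sorted(perm) == list(range(18))

    def test_unequal_families_raise(self, rng):
        with pytest.raises(ValueError):
            C.restricted_permutation(np.array([0, 0, 1]), rng)


class TestPermutationPvalues:
    def test_single_permutation_gives_one(self, rng):
        X = rng.standard_normal((12, 2))
        Y = rng.standard_normal((12, 2))
        p = C.permutation_pvalues(X, Y, np.repeat(np.arange(6), 2), n_perm=1)
        assert (p == 1.0).all()

    def test_perfect_signal_attains_minimum(self, rng):
        X = rng.standard_normal((16, 2))
        p = C.permutation_pvalues(X, X.copy(), np.repeat(np.arange(8), 2), n_perm=200, seed=1)
        assert p[0] == pytest.approx(1 / 200)

    def test_null_pvalues_roughly_uniform(self):
        """Independent X, Y: rejection at 0.05 happens about 5% of the time."""
        rng = np.random.default_rng(42)
        fam = np.repeat(np.arange(15), 2)
        hits = 0
        reps = 120
        for _ in range(reps):
            X = rng.standard_normal((30, 3))
            Y = rng.standard_normal((30, 3))
            p = C.permutation_pvalues(X, Y, fam, n_perm=100, seed=int(rng.integers(2**31)))
            hits += p[0] <= 0.05
        assert hits / reps < 0.15


class TestPartialCCA:
    def test_z_equal_x_reports_zero(self, rng):
        X = rng.standard_normal((30, 3))
        Y = rng.standard_normal((30, 3))
        res = C.partial_cca(X, Y, X.copy())
        np.testing.assert_allclose(res.r, 0.0, atol=1e-8)

    def test_orthogonal_z_equals_plain_cca(self, rng):
        Q = np.linalg.qr(rng.standard_normal((40, 8)))[0]
        X, Z = Q[:, :4], Q[:, 4:6]
        Y = rng.standard_normal((40, 3))
        # X and Z orthogonal and zero-mean-ish: residualising changes little
        res_partial = C.partial_cca(X, Y, Z)
        res_plain = C.cca_fit(C.deconfound(X, Z), Y)
        np.testing.assert_allclose(res_partial.r[:3], res_plain.r[:3], atol=1e-8)


class TestSurrogates:
    def test_surrogate_preserves_column_covariance(self, rng):
        X = rng.standard_normal((60, 5)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.2])
        sampler = C.MatrixNormalSurrogate(X)
        draws = np.array([sampler.draw(rng) for _ in range(800)])
        emp = np.mean([np.cov(d, rowvar=False) for d in draws], axis=0)
        Xc = X - X.mean(axis=0)
        target = Xc.T @ Xc / (X.shape[0] - 1)
        rel = np.linalg.norm(emp - target) / np.linalg.norm(target)
        assert rel < 0.2

    def test_ci_ordered_and_deterministic(self, rng):
        X = rng.standard_normal((40, 4))
        Y = rng.standard_normal((40, 4))
        lo, hi = C.surrogate_ci(X, Y, n_surr=60, seed=5)
        assert lo <= hi
        assert (lo, hi) == C.surrogate_ci(X, Y, n_surr=60, seed=5)

    def test_too_few_surrogates_raise(self, rng):
        with pytest.raises(ValueError):
            C.surrogate_ci(rng.standard_normal((20, 3)), rng.standard_normal((20, 3)), n_surr=10)


class TestModeInterpretation:
    def test_cross_mode_correlation_contains_reference(self, rng):
        U = rng.standard_normal((25, 4))
        assert C.cross_mode_correlation(U[:, 2], U) == pytest.approx(1.0)
        Q = np.linalg.qr(rng.standard_normal((50, 5)))[0]
        assert C.cross_mode_correlation(Q[:, 0], Q[:, 1:]) < 0.05

    def test_behaviour_loadings(self, rng):
        v = rng.standard_normal(40)
        B = np.column_stack([v, rng.standard_normal(40), np.full(40, 2.0)])
        loadings, strong = C.behaviour_loadings(v, B)
        assert loadings[0] == pytest.approx(1.0)
        assert np.isnan(loadings[2])
        assert 0 in strong

    def test_backprojection_exact_on_linear_features(self, rng):
        u = rng.standard_normal(30)
        a = rng.standard_normal(6)
        b = rng.standard_normal(6)
        F = a + np.outer(u, b)
        frames = C.backproject_mode(u, F, n_frames=5, extension=0.1)
        lo = u.min() - 0.1 * np.ptp(u)
        hi = u.max() + 0.1 * np.ptp(u)
        grid = np.linspace(lo, hi, 5)
        np.testing.assert_allclose(frames, a + np.outer(grid, b), atol=1e-8)
        with pytest.raises(ValueError):
            C.backproject_mode(np.ones(30), F)

    def test_weight_map_correlation(self, rng):
        N, G, M = 30, 20, 3
        w = rng.standard_normal(N)
        maps = [rng.standard_normal((G, M)) for _ in range(N)]
        for i, P in enumerate(maps):
            P[5, 1] = w[i]  # one grayordinate exactly tracks the weights
        out = C.weight_map_correlation(w, maps)
        assert out.shape == (G,)
        assert out[5] == pytest.approx(1.0)
        assert (out >= 0).all() and (out <= 1).all()


def test_cca_null_distribution_matches_jacobi_edge():
    """The null first canonical correlation of independent Gaussian blocks
    concentrates near the Jacobi-ensemble support edge
    2*sqrt(c(1-c)) for square blocks with c = K/N."""
    rng = np.random.default_rng(3)
    N, K = 200, 20
    c = K / N
    edge = 2 * np.sqrt(c * (1 - c))
    r1 = [
        C.first_canonical_correlation(rng.standard_normal((N, K)), rng.standard_normal((N, K)))
        for _ in range(40)
    ]
    assert abs(np.median(r1) - edge) < 0.08
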