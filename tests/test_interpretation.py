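"""Activation patterns, class weights, FVE and the frontal diagnostic."""

import numpy as np
import pytest

from megfix.errors import (
    DegenerateLatentsWarning,
    InsufficientDataError,
    UndefinedWeightsError,
)
from megfix.interpretation import (
    average_pattern,
    compute_patterns,
    frontal_diagnostic,
    fve_map,
    latent_timecourses,
    ls_class_weights,
)


def brute_force_patterns(W, X):
    """Independent oracle: explicit covariances and matrix inversion."""
    n_trials, n_channels, n_times = X.shape
    Xc = X.transpose(1, 0, 2).reshape(n_channels, -1)
    S = np.stack([W.T @ x for x in X]).transpose(1, 0, 2).reshape(W.shape[1], -1)
    sigma_X = np.cov(Xc)
    sigma_S = np.atleast_2d(np.cov(S))
    return np.atleast_2d(sigma_X) @ W @ np.linalg.inv(sigma_S)


def brute_force_class_weights(w, c):
    k = w.shape[1]
    denom = sum(abs(w[j, i, c]) for j in range(w.shape[0]) for i in range(k))
    return np.array([sum(abs(w[j, s, c]) for j in range(w.shape[0])) / denom for s in range(k)])


class TestLatentTimecourses:
    def test_identity_filter_returns_data(self):
        X = np.random.default_rng(0).normal(size=(3, 4, 10))
        np.testing.assert_allclose(latent_timecourses(np.eye(4), X), X)

    def test_basis_vector_selects_channel(self):
        X = np.random.default_rng(1).normal(size=(2, 4, 10))
        W = np.zeros((4, 1))
        W[2, 0] = 1.0
        np.testing.assert_allclose(latent_timecourses(W, X)[:, 0], X[:, 2])

    def test_equals_explicit_matrix_product(self):
        rng = np.random.default_rng(2)
        W, X = rng.normal(size=(4, 2)), rng.normal(size=(1, 4, 5))
        np.testing.assert_allclose(latent_timecourses(W, X)[0], W.T @ X[0])


class TestComputePatterns:
    def test_whitened_data_orthonormal_filters_give_patterns_equal_filters(self):
        # X with identity covariance: patterns reduce to the filters
        rng = np.random.default_rng(3)
        X = rng.normal(size=(1, 4, 200000))
        W, _ = np.linalg.qr(rng.normal(size=(4, 2)))
        ps = compute_patterns(W, X)
        np.testing.assert_allclose(ps.A, W, atol=0.05)

    def test_hand_worked_two_channel_example(self):
        # sigma_X = [[2,1],[1,1]], W = e1 -> sigma_S = 2, A = [[1],[0.5]]
        rng = np.random.default_rng(4)
        L = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 1.0]]))
        X = (L @ rng.normal(size=(2, 400000)))[None]
        W = np.array([[1.0], [0.0]])
        ps = compute_patterns(W, X)
        np.testing.assert_allclose(ps.A, [[1.0], [0.5]], atol=0.02)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(2, 6)
            k = rng.integers(1, min(4, n + 1))
            X = rng.normal(size=(rng.integers(1, 4), n, rng.integers(10, 30)))
            W = rng.normal(size=(n, k))
            ps = compute_patterns(W, X)
            np.testing.assert_allclose(ps.A, brute_force_patterns(W, X), atol=1e-8)

    def test_duplicate_filters_trigger_degenerate_warning(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(2, 4, 50))
        w = rng.normal(size=(4, 1))
        W = np.hstack([w, w])
        with pytest.warns(DegenerateLatentsWarning):
            ps = compute_patterns(W, X)
        assert ps.degenerate
        assert np.isfinite(ps.A).all()  # pseudo-inverse result still returned


class TestClassWeights:
    def test_uniform_tensor_gives_uniform_weights(self):
        w = np.ones((21, 16, 2))
        out = ls_class_weights(w, 1)
        np.testing.assert_allclose(out, 1 / 16)

    def test_one_hot_source(self):
        w = np.zeros((5, 8, 2))
        w[2, 3, 0] = -4.0
        out = ls_class_weights(w, 0)
        expect = np.zeros(8)
        expect[3] = 1.0
        np.testing.assert_array_equal(out, expect)

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(7)
        w = rng.normal(size=(2, 3, 2))
        for c in (0, 1):
            np.testing.assert_allclose(ls_class_weights(w, c), brute_force_class_weights(w, c), atol=1e-12)

    def test_sums_to_one_for_trained_model(self, trained_small_lf):
        model, _ = trained_small_lf
        for c in (0, 1):
            assert ls_class_weights(model.output_weights, c).sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_class_rejected(self):
        with pytest.raises(UndefinedWeightsError):
            ls_class_weights(np.zeros((3, 4, 2)), 1)


class TestAveragePattern:
    def test_uniform_average_of_basis_columns(self):
        from megfix.interpretation import PatternSet

        ps = PatternSet(A=np.eye(2), sigma_X=np.eye(2), sigma_S=np.eye(2), S_hat=np.zeros((1, 2, 3)))
        np.testing.assert_allclose(average_pattern(ps), [0.5, 0.5])

    def test_one_hot_weights_return_that_column(self):
        from megfix.interpretation import PatternSet

        rng = np.random.default_rng(8)
        A = rng.normal(size=(6, 3))
        ps = PatternSet(A=A, sigma_X=np.eye(6), sigma_S=np.eye(3), S_hat=np.zeros((1, 3, 4)))
        np.testing.assert_allclose(average_pattern(ps, np.array([0.0, 1.0, 0.0])), A[:, 1])

    def test_length_mismatch_rejected(self):
        from megfix.interpretation import PatternSet

        ps = PatternSet(A=np.eye(2), sigma_X=np.eye(2), sigma_S=np.eye(2), S_hat=np.zeros((1, 2, 3)))
        with pytest.raises(ValueError):
            average_pattern(ps, np.ones(3))


class TestFVE:
    def test_perfect_reconstruction_gives_unit_fve(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(3, 4, 40))
        ps = compute_patterns(np.eye(4), X)
        fm = fve_map(X, ps.A, ps.S_hat)
        np.testing.assert_allclose(fm.fve, 1.0, atol=1e-9)
        assert fm.full_fve == pytest.approx(1.0)

    def test_affine_reconstruction_still_unit_fve(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(2, 3, 50))
        S_hat = 2.0 * X + 3.0  # A = identity then X_rec = 2X + 3
        fm = fve_map(X, np.eye(3), S_hat)
        np.testing.assert_allclose(fm.fve, 1.0, atol=1e-9)

    def test_independent_noise_reconstruction_near_zero(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(1, 3, 10000))
        S_hat = rng.normal(size=(1, 3, 10000))
        fm = fve_map(X, np.eye(3), S_hat)
        assert np.all(fm.fve < 0.01)

    def test_constant_channel_flagged_and_excluded(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(1, 3, 100))
        X[:, 1, :] = 5.0
        fm = fve_map(X, np.eye(3), X.copy())
        assert not fm.valid[1] and np.isnan(fm.fve[1])
        assert fm.full_fve == pytest.approx(1.0)

    def test_full_fve_invariant_to_channel_reordering(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(2, 5, 60))
        W = rng.normal(size=(5, 2))
        ps = compute_patterns(W, X)
        fm = fve_map(X, ps.A, ps.S_hat)
        perm = rng.permutation(5)
        ps2 = compute_patterns(W[perm], X[:, perm])
        fm2 = fve_map(X[:, perm], ps2.A, ps2.S_hat)
        assert fm.full_fve == pytest.approx(fm2.full_fve, abs=1e-10)


class TestFrontalDiagnostic:
    def _patterns(self, A):
        from megfix.interpretation import PatternSet

        k = A.shape[1]
        return PatternSet(A=A, sigma_X=np.eye(A.shape[0]), sigma_S=np.eye(k), S_hat=np.zeros((1, k, 2)))

    def test_frontal_heavy_source_with_heavy_output_weight_gives_positive_r(self):
        rng = np.random.default_rng(14)
        A = np.abs(rng.normal(0.1, 0.02, size=(10, 4)))
        A[:3, 0] = 2.0  # source 0 loads on frontal channels
        w = np.full((5, 4, 2), 0.1)
        w[:, 0, 1] = 2.0  # and dominates the voluntary output weights
        mask = np.array([True] * 3 + [False] * 7)
        diag = frontal_diagnostic(self._patterns(A), w, mask, 1)
        assert diag.defined and diag.pearson_r > 0.9

    def test_constant_frontal_norms_flagged_undefined(self):
        A = np.ones((6, 3))
        w = np.random.default_rng(15).normal(size=(4, 3, 2))
        diag = frontal_diagnostic(self._patterns(A), w, np.array([True, True] + [False] * 4), 1)
        assert not diag.defined and np.isnan(diag.pearson_r)

    def test_empty_mask_rejected(self):
        A = np.ones((6, 3))
        with pytest.raises(InsufficientDataError):
            frontal_diagnostic(self._patterns(A), np.ones((4, 3, 2)), np.zeros(6, bool), 1)

    def test_too_few_sources_rejected(self):
        A = np.ones((6, 2))
        with pytest.raises(InsufficientDataError):
            frontal_diagnostic(self._patterns(A), np.ones((4, 2, 2)), np.ones(6, bool), 1)
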