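"""Canonical correlation core: decomposition, significance, loadings, S."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pathcca.cca import (
    CanonicalCorrelation,
    canonical_pvalues,
    compute_cca,
    correlation_matrix,
    structure_loadings,
    variance_extracted,
    zscore_columns,
)

from conftest import brute_force_first_canonical_r


def _random_instance(rng, n, p, q):
    M = zscore_columns(rng.standard_normal((n, p)))
    N = zscore_columns(rng.standard_normal((n, q)))
    return M, N


class TestZscore:
    def test_known_column(self):
        out = zscore_columns(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_idempotent(self, rng):
        X = zscore_columns(rng.standard_normal((20, 3)))
        np.testing.assert_allclose(zscore_columns(X), X, atol=1e-12)

    def test_constant_column_names_offender(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.raises(ValueError, match="gB"):
            zscore_columns(X, var_names=["gA", "gB"])

    @settings(derandomize=True, max_examples=25)
    @given(arrays(np.float64, (7, 3), elements=st.floats(-50, 50)))
    def test_moments(self, X):
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            with pytest.raises(ValueError):
                zscore_columns(X)
            return
        assume(np.all(sd > 1e-6))  # cancellation-dominated columns aside
        Z = zscore_columns(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, atol=1e-10)


class TestCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self, rng):
        R = correlation_matrix(rng.standard_normal((15, 4)))
        np.testing.assert_allclose(np.diag(R), 1.0)
        np.testing.assert_allclose(R, R.T)
        assert np.all(np.abs(R) <= 1.0)

    def test_perfect_anticorrelation(self):
        X = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])
        assert correlation_matrix(X)[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # dx.dy = 14, |dx| = sqrt(5), |dy| = sqrt(50) -> r = 14/sqrt(250)
        X = np.column_stack([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 10.0]])
        assert correlation_matrix(X)[0, 1] == pytest.approx(14 / np.sqrt(250), abs=1e-12)


class TestDecomposition:
    def test_1d_reduces_to_abs_pearson(self, rng):
        M, N = _random_instance(rng, 30, 1, 1)
        res = compute_cca(M, N)
        assert res.r[0] == pytest.approx(abs(np.corrcoef(M[:, 0], N[:, 0])[0, 1]),
                                         abs=1e-10)

    def test_identical_sets_give_unit_correlations(self, rng):
        M = zscore_columns(rng.standard_normal((25, 3)))
        res = compute_cca(M, M.copy())
        np.testing.assert_allclose(res.r, 1.0, atol=1e-10)

    def test_result_invariants(self, rng):
        M, N = _random_instance(rng, 40, 4, 3)
        res = compute_cca(M, N)
        assert len(res.r) == 3
        assert np.all(np.diff(res.r) <= 1e-12)           # descending
        assert np.all((res.r >= 0) & (res.r <= 1))
        np.testing.assert_allclose(res.U.std(axis=0, ddof=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(res.V.std(axis=0, ddof=1), 1.0, atol=1e-8)
        for k in range(3):
            assert np.corrcoef(res.U[:, k], res.V[:, k])[0, 1] == pytest.approx(
                res.r[k], abs=1e-10)
        cu = np.corrcoef(res.U, rowvar=False)
        cv = np.corrcoef(res.V, rowvar=False)
        np.testing.assert_allclose(cu - np.eye(3), 0, atol=1e-8)
        np.testing.assert_allclose(cv - np.eye(3), 0, atol=1e-8)

    def test_symmetry_in_set_order(self, rng):
        M, N = _random_instance(rng, 30, 3, 2)
        np.testing.assert_allclose(compute_cca(M, N).r, compute_cca(N, M).r, atol=1e-10)

    def test_affine_invariance(self, rng):
        M, N = _random_instance(rng, 30, 3, 3)
        T = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        res1 = compute_cca(M, N)
        res2 = CanonicalCorrelation(scale=True).fit(M, N @ T)
        np.testing.assert_allclose(res1.r, res2.correlations_, atol=1e-8)

    def test_first_r_bounds_any_column_pair(self, rng):
        for _ in range(10):
            M, N = _random_instance(rng, 20, 3, 3)
            res = compute_cca(M, N)
            best_pair = max(abs(np.corrcoef(M[:, i], N[:, j])[0, 1])
                            for i in range(3) for j in range(3))
            assert res.r[0] >= best_pair - 1e-10

    def test_matches_brute_force_oracle(self, rng):
        for i in range(10):
            n = int(rng.integers(7, 13))
            p = int(rng.integers(1, 4))
            q = int(rng.integers(1, 4))
            M, N = _random_instance(rng, n, p, q)
            res = compute_cca(M, N)
            oracle = brute_force_first_canonical_r(M, N, seed=i)
            assert res.r[0] == pytest.approx(oracle, abs=1e-6)

    def test_matches_sklearn_nipals(self, rng):
        # independent library route: sklearn's iterative CCA on a
        # well-conditioned instance agrees on the first correlation
        from sklearn.cross_decomposition import CCA as SkCCA

        M, N = _random_instance(rng, 200, 3, 3)
        res = compute_cca(M, N)
        sk = SkCCA(n_components=1, max_iter=2000).fit(M, N)
        u, v = sk.transform(M, N)
        assert res.r[0] == pytest.approx(abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1]),
                                         abs=1e-5)

    def test_deterministic_sign(self, rng):
        M, N = _random_instance(rng, 30, 3, 2)
        r1 = compute_cca(M, N)
        r2 = compute_cca(M.copy(), N.copy())
        np.testing.assert_array_equal(r1.AA, r2.AA)
        np.testing.assert_array_equal(r1.BB, r2.BB)
        # x-side convention: largest-|.| coefficient positive
        for j in range(r1.AA.shape[1]):
            col = r1.AA[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_mismatched_observations_error(self, rng):
        with pytest.raises(ValueError, match="observation counts"):
            compute_cca(rng.standard_normal((10, 2)), rng.standard_normal((9, 2)))

    def test_rank_deficient_duplicate_columns(self, rng):
        M = zscore_columns(rng.standard_normal((20, 2)))
        Mdup = np.column_stack([M, M[:, 0]])   # rank 2 in 3 columns
        N = zscore_columns(rng.standard_normal((20, 2)))
        res = compute_cca(Mdup, N)
        assert len(res.r) == 2


class TestSignificance:
    def test_null_correlations(self):
        sig = canonical_pvalues(np.zeros(2), 50, 2, 2)
        np.testing.assert_allclose(sig.wilks_lambda, 1.0)
        np.testing.assert_allclose(sig.chi_square, 0.0)
        np.testing.assert_allclose(sig.p_value, 1.0)

    def test_hand_computed_bartlett(self):
        # Lambda = 1 - 0.81 = 0.19; chi2 = -(50-1-1.5)*ln(0.19) = 78.8847; dof 1
        sig = canonical_pvalues(np.array([0.9]), 50, 1, 1)
        assert sig.wilks_lambda[0] == pytest.approx(0.19)
        assert sig.chi_square[0] == pytest.approx(-47.5 * np.log(0.19), rel=1e-12)
        assert sig.chi_square[0] == pytest.approx(78.88, abs=0.01)
        assert sig.dof[0] == 1

    def test_pvalue_decreases_in_r(self):
        ps = [canonical_pvalues(np.array([r, 0.1]), 100, 3, 3).p_value[0]
              for r in (0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_dof_sequence(self):
        sig = canonical_pvalues(np.array([0.5, 0.3, 0.1]), 100, 4, 3)
        np.testing.assert_array_equal(sig.dof, [12, 6, 2])

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            canonical_pvalues(np.array([1.2]), 50, 1, 1)

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="unreliable"):
            canonical_pvalues(np.array([0.5]), 5, 3, 3)


class TestLoadingsAndVarianceExtracted:
    def test_loadings_are_variate_variable_correlations(self, rng):
        M, N = _random_instance(rng, 50, 4, 3)
        res = compute_cca(M, N)
        r_1a, r_2b = structure_loadings(res)
        for k in range(len(res.r)):
            for j in range(4):
                assert r_1a[k, j] == pytest.approx(
                    np.corrcoef(res.U[:, k], M[:, j])[0, 1], abs=1e-8)
            for j in range(3):
                assert r_2b[k, j] == pytest.approx(
                    np.corrcoef(res.V[:, k], N[:, j])[0, 1], abs=1e-8)

    def test_single_variable_loading_is_unit(self, rng):
        M, N = _random_instance(rng, 30, 1, 2)
        r_1a, _ = structure_loadings(compute_cca(M, N))
        assert abs(r_1a[0, 0]) == pytest.approx(1.0, abs=1e-10)

    def test_variance_extracted_hand_example(self):
        assert variance_extracted(np.array([[0.6, 0.8]]), 0) == pytest.approx(0.5)

    def test_variance_extracted_bounds(self):
        assert variance_extracted(np.array([[1.0]]), 0) == 1.0
        assert variance_extracted(np.array([[0.0, 0.0]]), 0) == 0.0

    def test_variance_extracted_bad_input(self):
        with pytest.raises(ValueError):
            variance_extracted(np.empty((0, 0)), 0)
        with pytest.raises(ValueError):
            variance_extracted(np.array([[0.5]]), 3)


class TestEstimatorApi:
    def test_get_set_params_roundtrip(self):
        est = CanonicalCorrelation(reg=0.1)
        params = est.get_params()
        assert params["reg"] == 0.1
        est.set_params(reg=0.0, rank_tol=1e-8)
        assert est.rank_tol == 1e-8

    def test_fitted_attributes(self, rng):
        est = CanonicalCorrelation().fit(rng.standard_normal((30, 3)),
                                         rng.standard_normal((30, 2)))
        assert est.x_weights_.shape == (3, 2)
        assert est.y_weights_.shape == (2, 2)
        assert est.x_loadings_.shape == (2, 3)
        assert 0 <= est.variance_extracted_x_ <= 1
        assert 0 <= est.variance_extracted_y_ <= 1
        assert len(est.pvalues_) == 2
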