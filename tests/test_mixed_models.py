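"""REML estimation and mixed-model prediction, univariate and bivariate."""

import numpy as np
import pandas as pd
import pytest

from serrblup import (BivariateVarianceComponents, RelationshipMatrix,
                      VarianceComponents, estimate_bivariate_with_fallback,
                      fit_bivariate, fit_univariate, grm_vanraden,
                      reml_bivariate, reml_univariate, simulate_genotypes)


def _kernel(n, m, seed):
    return grm_vanraden(simulate_genotypes(n, m, seed=seed))


def _kernel_trait(K, rng, s2g=1.0, s2e=1.0):
    """y = g + e with g drawn exactly from N(0, s2g * K)."""
    n = K.n_lines
    L = np.linalg.cholesky(K.values + 1e-10 * np.eye(n))
    g = np.sqrt(s2g) * (L @ rng.standard_normal(n))
    return g + np.sqrt(s2e) * rng.standard_normal(n)


class TestRemlUnivariate:
    def test_recovers_simulated_components(self):
        errs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            K = _kernel(300, 500, seed)
            y = _kernel_trait(K, rng)
            vc = reml_univariate(y, K)
            errs.append([abs(vc.sigma2_g - 1), abs(vc.sigma2_eps - 1)])
        med = np.median(errs, axis=0)
        assert med[0] <= 0.25 and med[1] <= 0.25

    def test_constant_response_hits_boundary(self):
        K = _kernel(10, 20, 0)
        vc = reml_univariate(np.full(10, 2.5), K)
        assert vc.sigma2_g == 0.0 and vc.sigma2_eps == 0.0
        assert vc.mu_hat == pytest.approx(2.5)
        assert vc.converged

    def test_noise_free_limit_drives_ratio_to_zero(self):
        rng = np.random.default_rng(1)
        K = _kernel(300, 500, 1)
        y = _kernel_trait(K, rng, s2g=1.0, s2e=0.0)
        vc = reml_univariate(y, K)
        assert vc.sigma2_eps / vc.sigma2_g < 1e-3

    def test_invariant_to_kernel_scaling(self):
        rng = np.random.default_rng(2)
        K = _kernel(80, 100, 2)
        y = _kernel_trait(K, rng)
        vc1 = reml_univariate(y, K)
        K10 = RelationshipMatrix(K.line_ids, 10 * K.values, "VR", K.normalizer)
        vc2 = reml_univariate(y, K10)
        assert vc2.sigma2_g == pytest.approx(vc1.sigma2_g / 10, rel=1e-3)
        assert vc2.sigma2_eps == pytest.approx(vc1.sigma2_eps, rel=1e-3)

    def test_too_few_lines_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            reml_univariate(np.ones(2), np.eye(2))


class TestFitUnivariate:
    def test_identity_kernel_hand_solution(self):
        gamma = RelationshipMatrix(["a", "b"], np.eye(2), "VR", 1.0)
        pred = fit_univariate(np.array([1.0, -1.0]), gamma,
                              VarianceComponents(1.0, 1.0, 0.0))
        assert pred.mu_hat == pytest.approx(0.0)
        np.testing.assert_allclose(pred.g_hat, [0.5, -0.5])

    def test_infinite_shrinkage_predicts_the_mean(self):
        rng = np.random.default_rng(3)
        K = _kernel(20, 30, 3)
        y = rng.normal(0, 1, 15)
        vc = VarianceComponents(1.0, 1e8, 0.0)
        pred = fit_univariate(y, K, vc, np.arange(15))
        np.testing.assert_allclose(pred.g_hat, 0.0, atol=1e-6)
        np.testing.assert_allclose(pred.y_hat, y.mean(), atol=1e-6)

    def test_duplicated_kernel_row_duplicates_prediction(self):
        rng = np.random.default_rng(4)
        K = _kernel(12, 40, 4)
        V = K.values.copy()
        V[11] = V[0]
        V[:, 11] = V[:, 0]
        K2 = RelationshipMatrix(K.line_ids, V, "VR", K.normalizer)
        y = rng.normal(0, 1, 11)
        pred = fit_univariate(y, K2, VarianceComponents(1.0, 0.5, 0.0),
                              np.arange(11))
        assert pred.g_hat[11] == pytest.approx(pred.g_hat[0], abs=1e-10)

    def test_matches_dense_mme_solve(self):
        """Inverse-free form equals the direct mixed-model-equation solve."""
        rng = np.random.default_rng(5)
        n, n1 = 12, 8
        K = _kernel(n, 40, 5)
        y = rng.normal(0, 1, n1)
        s2g, s2e = 1.3, 0.6
        lam = s2e / s2g
        pred = fit_univariate(y, K, VarianceComponents(s2g, s2e, 0.0),
                              np.arange(n1))
        Ki = np.linalg.inv(K.values + 1e-10 * np.eye(n))
        C = np.zeros((n + 1, n + 1))
        C[0, 0] = n1
        C[0, 1:n1 + 1] = 1.0
        C[1:n1 + 1, 0] = 1.0
        C[1:, 1:] = lam * Ki
        C[1:n1 + 1, 1:n1 + 1] += np.eye(n1)
        rhs = np.concatenate([[y.sum()], y, np.zeros(n - n1)])
        sol = np.linalg.solve(C, rhs)
        assert pred.mu_hat == pytest.approx(sol[0], abs=1e-6)
        np.testing.assert_allclose(pred.g_hat, sol[1:], atol=1e-6)

    def test_shift_invariance_of_genetic_values(self):
        rng = np.random.default_rng(6)
        K = _kernel(15, 30, 6)
        y = rng.normal(0, 1, 15)
        vc = VarianceComponents(1.0, 1.0, 0.0)
        p1 = fit_univariate(y, K, vc)
        p2 = fit_univariate(y + 100.0, K, vc)
        np.testing.assert_allclose(p1.g_hat, p2.g_hat, atol=1e-8)

    def test_no_training_lines_rejected(self):
        K = _kernel(5, 10, 7)
        with pytest.raises(ValueError, match="no training"):
            fit_univariate(np.empty(0), K, VarianceComponents(1, 1, 0),
                           np.array([], dtype=int))


class TestRemlBivariate:
    def test_zero_genetic_correlation_recovered(self):
        vals = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            K = _kernel(150, 300, seed)
            n = K.n_lines
            L = np.linalg.cholesky(K.values + 1e-10 * np.eye(n))
            y1 = pd.Series(L @ rng.standard_normal(n)
                           + rng.standard_normal(n), index=K.line_ids)
            y2 = pd.Series(L @ rng.standard_normal(n)
                           + rng.standard_normal(n), index=K.line_ids)
            bv = reml_bivariate(y1, y2, K, max_iter=80)
            denom = np.sqrt(bv.H[0, 0] * bv.H[1, 1])
            vals.append(abs(bv.H[0, 1]) / denom)
        assert np.mean(vals) < 0.15

    def test_duplicated_environment_hits_correlation_boundary(self):
        rng = np.random.default_rng(11)
        K = _kernel(60, 100, 11)
        y = pd.Series(_kernel_trait(K, rng), index=K.line_ids)
        bv = reml_bivariate(y, y.copy(), K, max_iter=60)
        assert bv.genetic_correlation > 0.98  # PSD clipping keeps it finite
        bv.check_psd()

    def test_single_iteration_contract(self):
        rng = np.random.default_rng(12)
        K = _kernel(30, 50, 12)
        y1 = pd.Series(rng.normal(0, 1, 30), index=K.line_ids)
        y2 = pd.Series(rng.normal(0, 1, 30), index=K.line_ids)
        bv = reml_bivariate(y1, y2, K, max_iter=1)
        assert bv.n_iter == 1 and not bv.converged

    def test_unknown_line_rejected(self):
        K = _kernel(5, 10, 13)
        y = pd.Series(np.ones(3), index=["Z1", "Z2", "Z3"])
        with pytest.raises(ValueError, match="not in kernel"):
            reml_bivariate(y, y, K)


class TestFitBivariate:
    def _data(self, seed, n=10, k=6):
        rng = np.random.default_rng(seed)
        K = _kernel(n, 30, seed)
        ids = K.line_ids
        y1 = pd.Series(rng.normal(0, 1, n), index=ids)
        y2 = pd.Series(rng.normal(0, 1, k), index=ids[:k])
        return K, ids, y1, y2, ids[k:]

    def test_diagonal_components_decouple_to_univariate(self):
        K, ids, y1, y2, masked = self._data(20)
        bvc = BivariateVarianceComponents(np.diag([1.0, 1.4]),
                                          np.diag([0.7, 0.9]))
        pred = fit_bivariate(y1, y2, masked, K, bvc)
        uni = fit_univariate(y2.to_numpy(), K,
                             VarianceComponents(1.4, 0.9, 0.0), np.arange(6))
        np.testing.assert_allclose(pred.y_hat,
                                   uni.mu_hat + uni.g_hat[6:], atol=1e-8)

    def test_matches_dense_mme_with_kronecker_covariance(self):
        K, ids, y1, y2, masked = self._data(21, n=8, k=5)
        n, k = 8, 5
        H = np.array([[1.0, 0.5], [0.5, 1.2]])
        R0 = np.array([[0.8, 0.2], [0.2, 0.9]])
        pred = fit_bivariate(y1, y2, masked, K,
                             BivariateVarianceComponents(H, R0))
        ridge = 1e-8 * np.mean(np.diag(K.values))
        G = np.kron(H, K.values + ridge * np.eye(n))
        Z = np.zeros((n + k, 2 * n))
        Z[:n, :n] = np.eye(n)
        Z[n:, n:n + k] = np.eye(k)
        X = np.zeros((n + k, 2))
        X[:n, 0] = 1.0
        X[n:, 1] = 1.0
        R = R0[0, 0] * np.eye(n + k)
        for i in range(k):
            R[n + i, n + i] = R0[1, 1]
            R[i, n + i] = R[n + i, i] = R0[0, 1]
        Ri = np.linalg.inv(R)
        C = np.block([[X.T @ Ri @ X, X.T @ Ri @ Z],
                      [Z.T @ Ri @ X, Z.T @ Ri @ Z + np.linalg.inv(G)]])
        yv = np.concatenate([y1.to_numpy(), y2.to_numpy()])
        rhs = np.concatenate([X.T @ Ri @ yv, Z.T @ Ri @ yv])
        sol = np.linalg.solve(C, rhs)
        y_hat_oracle = sol[1] + sol[2 + n + k:]
        np.testing.assert_allclose(pred.y_hat, y_hat_oracle, atol=1e-6)

    def test_empty_mask_returns_genetic_values_only(self):
        K, ids, y1, y2, _ = self._data(22)
        bvc = BivariateVarianceComponents(np.diag([1.0, 1.0]),
                                          np.diag([1.0, 1.0]))
        pred = fit_bivariate(y1, y2, [], K, bvc)
        assert pred.y_hat.size == 0 and pred.g_hat.size == K.n_lines

    def test_non_psd_components_rejected(self):
        K, ids, y1, y2, masked = self._data(23)
        bad = BivariateVarianceComponents(np.array([[1.0, 2.0], [2.0, 1.0]]),
                                          np.eye(2))
        with pytest.raises(ValueError, match="positive semidefinite"):
            fit_bivariate(y1, y2, masked, K, bad)


class TestFallbackProtocol:
    def test_pathological_data_engages_fallback(self):
        rng = np.random.default_rng(30)
        K = _kernel(10, 40, 30)
        ids = K.line_ids
        y1 = pd.Series(rng.normal(0, 1, 10), index=ids)
        y2 = pd.Series(rng.normal(0, 1, 10), index=ids)
        folds = [ids[:8], ids[2:], ids[1:9]]
        res = estimate_bivariate_with_fallback(y1, y2, K, folds,
                                               max_iter_full=10,
                                               max_iter_fold=2)
        assert len(res.folds) == 3
        assert all(f.fixed_fallback_used for f in res.folds)
        for f in res.folds:
            np.testing.assert_array_equal(f.H, res.full.H)
            np.testing.assert_array_equal(f.R0, res.full.R0)

    def test_fold_estimates_stay_close_to_full_data_estimates(self):
        """Training-subset components deviate little from full-data ones."""
        rng = np.random.default_rng(31)
        K = _kernel(200, 400, 31)
        ids = K.line_ids
        n = K.n_lines
        L = np.linalg.cholesky(K.values + 1e-10 * np.eye(n))
        shared = L @ rng.standard_normal(n)
        y1 = pd.Series(shared + 0.5 * (L @ rng.standard_normal(n))
                       + rng.standard_normal(n), index=ids)
        y2 = pd.Series(shared + 0.5 * (L @ rng.standard_normal(n))
                       + rng.standard_normal(n), index=ids)
        folds = [ids[:160], ids[40:]]
        res = estimate_bivariate_with_fallback(y1, y2, K, folds,
                                               max_iter_full=50,
                                               max_iter_fold=50)
        for f in res.folds:
            rel = np.abs(np.diag(f.H) - np.diag(res.full.H)) / np.diag(res.full.H)
            assert (rel < 0.25).all()
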