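import numpy as np
import pytest
from scipy.stats import multivariate_normal

from azogp import gp
from azogp.gp import (
    Coregionalisation,
    DegenerateTargetError,
    GPConfig,
    GPState,
    KernelParams,
    fit_gp,
    icm_covariance,
    log_marginal_likelihood,
    predict_gp,
    tanimoto_kernel,
    tanimoto_matrix,
)


def random_fragprints(rng, n, d=24):
    bits = rng.binomial(1, 0.3, size=(n, d // 2))
    counts = rng.poisson(1.0, size=(n, d - d // 2))
    X = np.hstack([bits, counts]).astype(float)
    X[~X.any(axis=1), 0] = 1.0
    return X


class TestTanimotoKernel:
    def test_self_similarity_is_signal_variance(self):
        assert tanimoto_kernel([1, 1, 0], [1, 1, 0], 1.0) == pytest.approx(1.0)
        assert tanimoto_kernel([0, 2, 5], [0, 2, 5], 3.7) == pytest.approx(3.7)

    def test_disjoint_supports_give_zero(self):
        assert tanimoto_kernel([1, 1, 0], [0, 0, 1]) == 0.0

    def test_hand_evaluated_example(self):
        # <x,x'> = 1, |x|^2 = |x'|^2 = 2 -> 2 * 1/(2+2-1) = 2/3
        assert tanimoto_kernel([1, 1, 0], [1, 0, 1], 2.0) == pytest.approx(2 / 3)

    def test_both_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            tanimoto_kernel([0, 0], [0, 0])

    def test_matrix_symmetric_and_psd(self):
        rng = np.random.default_rng(0)
        X = random_fragprints(rng, 40)
        T = tanimoto_matrix(X)
        np.testing.assert_allclose(T, T.T)
        np.testing.assert_allclose(np.diag(T), 1.0)
        assert np.linalg.eigvalsh(T).min() > -1e-9


class TestLogMarginalLikelihood:
    def test_univariate_oracle(self):
        x = np.array([[1.0, 1.0]])  # t(x,x) = 1
        p = KernelParams(sigma_f2=1.0, sigma_y2=0.0)
        assert log_marginal_likelihood(p, x, [0.0]) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-6)
        assert log_marginal_likelihood(p, x, [1.0]) == pytest.approx(
            -0.5 - 0.5 * np.log(2 * np.pi), abs=1e-6)

    @pytest.mark.parametrize("n,seed", [(5, 0), (20, 1), (50, 2)])
    def test_matches_dense_multivariate_normal_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        X = random_fragprints(rng, n)
        y = rng.standard_normal(n)
        p = KernelParams(sigma_f2=1.4, sigma_y2=0.3)
        K = 1.4 * tanimoto_matrix(X) + 0.3 * np.eye(n)
        oracle = multivariate_normal(mean=np.zeros(n), cov=K).logpdf(y)
        assert log_marginal_likelihood(p, X, y) == pytest.approx(
            oracle, abs=1e-8)


class TestFitGP:
    def test_fitted_params_are_a_stationary_point(self, synth_small):
        X, Y, _ = synth_small
        state = fit_gp(X, Y[:, 0], GPConfig(n_restarts=3, seed=0))
        z = state.z
        best = log_marginal_likelihood(state.params, X, z)
        for df, dn in [(1.05, 1.0), (0.95, 1.0), (1.0, 1.2), (1.0, 0.8)]:
            p = KernelParams(state.params.sigma_f2 * df,
                             max(state.params.sigma_y2, 1e-8) * dn)
            assert log_marginal_likelihood(p, X, z) <= best + 1e-6

    def test_two_identical_molecules_distinct_targets(self):
        X = np.array([[1.0, 2.0, 0.0], [1.0, 2.0, 0.0]])
        state = fit_gp(X, [300.0, 320.0], GPConfig(n_restarts=2, seed=0))
        assert state.params.sigma_y2 > 1e-4  # noise absorbs disagreement

    def test_constant_targets_rejected(self):
        X = np.eye(3)
        with pytest.raises(DegenerateTargetError):
            fit_gp(X, [5.0, 5.0, 5.0])

    def test_affine_target_rescaling_leaves_predictions_equivariant(
            self, synth_small):
        X, Y, _ = synth_small
        y = 400.0 + 60.0 * Y[:, 0]
        cfg = GPConfig(n_restarts=3, seed=1)
        m1, v1 = predict_gp(fit_gp(X, y, cfg), X[:10])
        m2, v2 = predict_gp(fit_gp(X, 2.0 * y - 30.0, cfg), X[:10])
        np.testing.assert_allclose(m2, 2.0 * m1 - 30.0, rtol=1e-6)
        np.testing.assert_allclose(v2, 4.0 * v1, rtol=1e-5, atol=1e-10)


class TestPredictGP:
    @staticmethod
    def manual_state(X, y, sigma_f2=1.0, sigma_y2=0.0):
        from scipy.linalg import cholesky, solve_triangular

        y = np.asarray(y, dtype=float)
        K = sigma_f2 * tanimoto_matrix(X) + sigma_y2 * np.eye(len(y))
        L = cholesky(K + 1e-10 * np.eye(len(y)), lower=True)
        alpha = solve_triangular(L.T, solve_triangular(L, y, lower=True),
                                 lower=False)
        return GPState(X_train=np.asarray(X, float), y_mean=0.0, y_std=1.0,
                       params=KernelParams(sigma_f2, sigma_y2), chol=L,
                       alpha=alpha, z=y, jitter=1e-10)

    def test_noiseless_interpolation(self, synth_small):
        X, Y, _ = synth_small
        state = self.manual_state(X[:20], Y[:20, 0])
        mean, var = predict_gp(state, X[:20])
        np.testing.assert_allclose(mean, Y[:20, 0], atol=1e-4)
        assert np.all(var < 1e-4)

    def test_prior_reversion_for_disjoint_query(self):
        X = np.array([[1.0, 1.0, 0.0, 0.0], [1.0, 0.0, 1.0, 0.0]])
        state = self.manual_state(X, [1.0, -1.0], sigma_f2=2.0,
                                  sigma_y2=0.1)
        state.y_mean, state.y_std = 350.0, 10.0
        mean, var = predict_gp(state, [[0.0, 0.0, 0.0, 1.0]])
        assert mean[0] == pytest.approx(350.0)          # training-target mean
        assert var[0] == pytest.approx(2.0 * 100.0)     # prior sigma_f2

    def test_two_point_toy_matches_hand_linear_algebra(self):
        # x1=(1,1,0), x2=(1,0,1): K = [[1, 1/3], [1/3, 1]]
        X = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 1.0]])
        y = np.array([2.0, -1.0])
        state = self.manual_state(X, y, sigma_f2=1.0, sigma_y2=0.5)
        x_star = np.array([[0.0, 1.0, 1.0]])  # k(x*,x1)=k(x*,x2)=1/3
        K = np.array([[1.5, 1 / 3], [1 / 3, 1.5]])
        k_star = np.array([1 / 3, 1 / 3])
        mean_hand = k_star @ np.linalg.inv(K) @ y
        var_hand = 1.0 - k_star @ np.linalg.inv(K) @ k_star
        mean, var = predict_gp(state, x_star)
        assert mean[0] == pytest.approx(mean_hand, abs=1e-8)
        assert var[0] == pytest.approx(var_hand, abs=1e-7)

    def test_variance_never_increases_with_added_observation(self):
        rng = np.random.default_rng(4)
        X = random_fragprints(rng, 15)
        y = rng.standard_normal(15)
        x_star = random_fragprints(rng, 1)
        base = self.manual_state(X, y, sigma_y2=0.2)
        _, var_before = predict_gp(base, x_star)
        grown = self.manual_state(np.vstack([X, x_star]),
                                  np.append(y, 0.0), sigma_y2=0.2)
        _, var_after = predict_gp(grown, x_star)
        assert var_after[0] <= var_before[0] + 1e-10

    def test_dimension_mismatch(self, synth_small):
        X, Y, _ = synth_small
        state = fit_gp(X, Y[:, 0], GPConfig(n_restarts=1, seed=0))
        with pytest.raises(ValueError, match="dimension"):
            predict_gp(state, np.ones((2, X.shape[1] + 1)))


class TestICMCovariance:
    def test_identity_B_zeroes_cross_task(self):
        coreg = Coregionalisation(L=np.eye(4))
        x, x2 = [1, 1, 0], [1, 0, 1]
        p = KernelParams(1.0, 0.0)
        assert icm_covariance(x, x2, 0, 1, p, coreg) == 0.0
        assert icm_covariance(x, x2, 2, 2, p, coreg) == pytest.approx(1 / 3)

    def test_hand_LLT_example(self):
        L = np.zeros((4, 4))
        L[0, 0], L[1, 0], L[1, 1] = 1.0, 0.5, 2.0
        L[2, 2] = L[3, 3] = 1.0
        B = Coregionalisation(L=L).B
        assert B[0, 1] == pytest.approx(0.5)
        assert B[1, 1] == pytest.approx(4.25)

    def test_unit_Bii_reduces_to_single_task_kernel(self):
        coreg = Coregionalisation(L=np.eye(4))
        p = KernelParams(2.0, 0.0)
        x, x2 = [1, 1, 0], [1, 0, 1]
        assert icm_covariance(x, x2, 1, 1, p, coreg) == pytest.approx(
            tanimoto_kernel(x, x2, 2.0))

    def test_symmetry_under_joint_swap(self):
        L = np.tril(np.random.default_rng(0).uniform(0.1, 1.0, (4, 4)))
        coreg = Coregionalisation(L=L)
        p = KernelParams(1.3, 0.0)
        a = icm_covariance([1, 2, 0], [0, 1, 3], 0, 2, p, coreg)
        b = icm_covariance([0, 1, 3], [1, 2, 0], 2, 0, p, coreg)
        assert a == pytest.approx(b)

    def test_non_lower_triangular_rejected(self):
        with pytest.raises(ValueError, match="lower-triangular"):
            Coregionalisation(L=np.ones((4, 4)))


class TestSerialisation:
    def test_gp_roundtrip(self, synth_small, tmp_path):
        X, Y, _ = synth_small
        state = fit_gp(X, Y[:, 0], GPConfig(n_restarts=2, seed=0))
        path = tmp_path / "model.azogp"
        gp.save_model(state, path, feature_config={"n_bits": 8})
        loaded = gp.load_model(path)
        m0, v0 = predict_gp(state, X[:5])
        m1, v1 = predict_gp(loaded, X[:5])
        np.testing.assert_allclose(m1, m0, atol=1e-8)
        np.testing.assert_allclose(v1, v0, atol=1e-8)

    def test_mogp_roundtrip(self, synth_small, tmp_path):
        X, Y, _ = synth_small
        obs = gp.observations_from_table(Y[:30])
        state = gp.fit_mogp(obs, X[:30], gp.MOGPConfig(n_restarts=1, seed=0))
        path = tmp_path / "model.azogp"
        gp.save_model(state, path)
        loaded = gp.load_model(path)
        for task in range(4):
            m0, v0 = gp.predict_mogp(state, X[30:35], task)
            m1, v1 = gp.predict_mogp(loaded, X[30:35], task)
            np.testing.assert_allclose(m1, m0, atol=1e-8)
            np.testing.assert_allclose(v1, v0, atol=1e-8)
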