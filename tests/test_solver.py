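import numpy as np
import pytest

from slaprvfl import (
    Hyperparameters,
    SLapRVFLRegressor,
    generate_sparse_linear,
    l21_norm,
    normalized_laplacian,
    objective,
    rbf_similarity,
    ridge_solve,
    row_norm_weights,
    slaprvfl_step,
)


@pytest.fixture()
def instance(rng):
    H = rng.standard_normal((15, 5))
    Y = rng.standard_normal((15, 1))
    L = normalized_laplacian(rbf_similarity(rng.standard_normal((15, 3)), 0.5))
    return H, Y, L


class TestObjective:
    def test_zero_beta_keeps_only_data_term(self, instance):
        H, Y, L = instance
        val = objective(H, Y, L, np.zeros((5, 1)), 0.3, 0.7)
        assert val == pytest.approx(0.5 * np.linalg.norm(Y) ** 2, abs=1e-12)

    def test_reduces_to_least_squares(self, instance, rng):
        H, Y, L = instance
        beta = rng.standard_normal((5, 1))
        val = objective(H, Y, None, beta, 0.0, 0.0)
        assert val == pytest.approx(
            0.5 * np.linalg.norm(H @ beta - Y) ** 2, abs=1e-10
        )

    def test_matches_term_by_term_oracle(self, instance, rng):
        H, Y, L = instance
        beta = rng.standard_normal((5, 1))
        lam1, lam2 = 0.4, 0.9
        # independent summation oracle: explicit loops
        pred = H @ beta
        data = 0.5 * sum(
            (pred[i, j] - Y[i, j]) ** 2
            for i in range(15)
            for j in range(1)
        )
        lap = 0.5 * lam1 * sum(
            pred[i, 0] * L[i, k] * pred[k, 0] for i in range(15) for k in range(15)
        )
        sparse = 0.5 * lam2 * sum(
            np.sqrt(sum(beta[i, j] ** 2 for j in range(1))) for i in range(5)
        )
        assert objective(H, Y, L, beta, lam1, lam2) == pytest.approx(
            data + lap + sparse, abs=1e-10
        )

    def test_shape_mismatch_raises(self, instance):
        H, Y, L = instance
        with pytest.raises(ValueError):
            objective(H, Y, L, np.zeros((4, 1)), 0.1, 0.1)


class TestRowNormWeights:
    def test_hand_norm(self):
        g = row_norm_weights(np.array([[3.0, 4.0]]), epsilon=1e-12)
        assert g[0] == pytest.approx(0.1, rel=1e-9)

    def test_zero_row_guard(self):
        g = row_norm_weights(np.zeros((1, 2)), epsilon=1e-8)
        assert g[0] == pytest.approx(5e7)
        assert np.isfinite(g[0])

    def test_scaling_homogeneity(self, rng):
        beta = rng.standard_normal((6, 2))
        g1 = row_norm_weights(beta, epsilon=1e-12)
        g10 = row_norm_weights(10 * beta, epsilon=1e-12)
        assert np.allclose(g1 / g10, 10.0, rtol=1e-6)

    def test_monotone_in_row_norm(self, rng):
        beta = rng.standard_normal((8, 3))
        g = row_norm_weights(beta)
        norms = np.linalg.norm(beta, axis=1)
        order = np.argsort(norms)
        assert np.all(np.diff(g[order]) <= 0)

    def test_epsilon_required(self):
        with pytest.raises(ValueError):
            row_norm_weights(np.ones((2, 2)), epsilon=0.0)


class TestStep:
    def test_reduces_to_ridge_with_identity_weights(self, instance):
        H, Y, L = instance
        lam = 0.8
        beta_step = slaprvfl_step(H, Y, None, np.ones(5), 0.0, lam)
        beta_ridge = ridge_solve(H, Y, lam)
        assert np.allclose(beta_step, beta_ridge, atol=1e-10)

    def test_unregularized_limit_is_least_squares(self, instance):
        H, Y, L = instance
        beta = slaprvfl_step(H, Y, None, np.ones(5), 0.0, 0.0)
        ls, *_ = np.linalg.lstsq(H, Y, rcond=None)
        assert np.allclose(beta, ls, atol=1e-8)

    def test_stationarity_oracle(self, instance, rng):
        H, Y, L = instance
        g = np.abs(rng.standard_normal(5)) + 0.1
        lam1, lam2 = 0.3, 0.6
        beta = slaprvfl_step(H, Y, L, g, lam1, lam2)
        lhs = (H.T @ H + lam1 * H.T @ L @ H + lam2 * np.diag(g)) @ beta
        rhs = H.T @ Y
        assert np.linalg.norm(lhs - rhs) <= 1e-8 * np.linalg.norm(rhs)


class TestFit:
    def test_objective_trace_nonincreasing(self, small_cohort):
        X, y = small_cohort
        model = SLapRVFLRegressor(
            hyper=Hyperparameters(P=30, max_iter=15, tol=0.0)
        ).fit(X, y)
        obj = np.asarray(model.trace_.objectives)
        assert np.all(np.diff(obj) <= 1e-8 * np.abs(obj[:-1]))

    def test_fixed_point_stationarity(self, small_cohort):
        X, y = small_cohort
        h = Hyperparameters(P=20, max_iter=200, tol=1e-12)
        model = SLapRVFLRegressor(hyper=h).fit(X, y)
        # recompute the stationarity system with G at the returned beta
        from slaprvfl.rvfl import apply_standardization, build_design_matrix

        Z = apply_standardization(X, model.scaler_)
        H = build_design_matrix(Z, model.hidden_).H
        L = normalized_laplacian(rbf_similarity(Z, model.gamma_))
        g = row_norm_weights(model.beta_, model.epsilon)
        Yc = (y - model.y_mean_)[:, None]
        lhs = (
            H.T @ H + h.lambda1 * H.T @ L @ H + h.lambda2 * np.diag(g)
        ) @ model.beta_
        rhs = H.T @ Yc
        assert np.linalg.norm(lhs - rhs) <= 1e-6 * np.linalg.norm(rhs)

    def test_single_iteration_unregularized_is_least_squares(self, rng):
        X = rng.standard_normal((60, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 0.01 * rng.standard_normal(60)
        h = Hyperparameters(P=5, lambda_ridge=0.0, lambda1=0.0, lambda2=0.0,
                            max_iter=1)
        model = SLapRVFLRegressor(hyper=h).fit(X, y)
        from slaprvfl.rvfl import apply_standardization, build_design_matrix

        Z = apply_standardization(X, model.scaler_)
        H = build_design_matrix(Z, model.hidden_).H
        ls, *_ = np.linalg.lstsq(H, y - y.mean(), rcond=None)
        assert np.allclose(model.beta_[:, 0], ls, atol=1e-7)

    def test_lambda1_limit_matches_ridge_refit(self, small_cohort):
        # one reweighting step from G = I at lambda1 -> 0 equals a ridge solve
        X, y = small_cohort
        h = Hyperparameters(P=10, lambda1=1e-12, lambda2=0.5, max_iter=1)
        model = SLapRVFLRegressor(hyper=h).fit(X, y)
        h0 = Hyperparameters(P=10, lambda1=0.0, lambda2=0.5, max_iter=1)
        model0 = SLapRVFLRegressor(hyper=h0).fit(X, y)
        assert np.allclose(model.beta_, model0.beta_, atol=1e-6)

    def test_determinism(self, small_cohort):
        X, y = small_cohort
        h = Hyperparameters(P=25, seed=3)
        m1 = SLapRVFLRegressor(hyper=h).fit(X, y)
        m2 = SLapRVFLRegressor(hyper=h).fit(X, y)
        assert np.array_equal(m1.beta_, m2.beta_)
        assert m1.trace_.objectives == m2.trace_.objectives

    def test_row_permutation_leaves_heldout_predictions(self, rng):
        from slaprvfl import default_cohort_spec, generate_cohort

        X, y = generate_cohort(default_cohort_spec(n=60, seed=5))
        X_new, _ = generate_cohort(default_cohort_spec(n=10, seed=6))
        perm = rng.permutation(60)
        h = Hyperparameters(P=15, seed=0)
        p1 = SLapRVFLRegressor(hyper=h).fit(X, y).predict(X_new)
        p2 = SLapRVFLRegressor(hyper=h).fit(X[perm], y[perm]).predict(X_new)
        assert np.allclose(p1, p2, atol=1e-8)

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            SLapRVFLRegressor().fit(np.zeros((1, 3)), np.zeros(1))

    def test_invalid_hyperparameters_raise(self):
        with pytest.raises(ValueError):
            Hyperparameters(max_iter=0)
        with pytest.raises(ValueError):
            Hyperparameters(lambda1=-0.1)
        with pytest.raises(ValueError):
            Hyperparameters(P=0)

    def test_sparse_rows_suppressed(self):
        # only 3 of 10 inputs drive the target; the L2,1 penalty should
        # leave the inactive direct-link rows with far smaller norms
        X, y, support = generate_sparse_linear(200, 10, 3, noise_sd=0.1, seed=7)
        h = Hyperparameters(P=20, lambda1=0.0, lambda2=4.0, max_iter=30, seed=0)
        model = SLapRVFLRegressor(hyper=h).fit(X, y)
        norms = model.input_row_norms()
        active = norms[support]
        inactive = np.delete(norms, support)
        assert active.min() >= 10.0 * inactive.max()


def test_l21_norm(rng):
    beta = np.array([[3.0, 4.0], [0.0, 1.0]])
    assert l21_norm(beta) == pytest.approx(6.0)
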