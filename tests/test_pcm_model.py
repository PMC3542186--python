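import numpy as np
import pytest

from hdacpcm import (
    PukParams,
    SVRParams,
    TrainedPCMModel,
    cross_validate,
    gram_matrix,
    predict,
    puk_kernel,
    q_squared,
    train_svr,
)


class TestPukKernel:
    def test_zero_distance_is_one(self):
        x = np.array([1.0, -2.0, 3.0])
        assert puk_kernel(x, x) == pytest.approx(1.0)

    def test_closed_form_omega1(self):
        # omega=1, sigma=1, distance 0.5 -> 1/(1+1) = 0.5
        assert puk_kernel([0.0, 0.0], [0.5, 0.0], PukParams(1.0, 1.0)) == pytest.approx(0.5)

    def test_closed_form_omega2(self):
        # omega=2, sigma=1, distance 1 -> (1 + 4(sqrt(2)-1))^-2
        expected = (1.0 + 4.0 * (np.sqrt(2.0) - 1.0)) ** -2  # = 0.1416656...
        assert puk_kernel([0.0], [1.0], PukParams(2.0, 1.0)) == pytest.approx(expected, abs=1e-12)

    def test_range_symmetry_monotonicity(self):
        rng = np.random.default_rng(1)
        params = PukParams(1.5, 0.8)
        prev = 1.0
        for d in np.linspace(0.1, 5.0, 20):
            x, y = np.zeros(4), np.zeros(4)
            y[0] = d
            k = puk_kernel(x, y, params)
            assert 0.0 < k < 1.0
            assert k == pytest.approx(puk_kernel(y, x, params))
            assert k < prev
            prev = k

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            puk_kernel([1.0, 2.0], [1.0])

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            PukParams(omega=0.0)
        with pytest.raises(ValueError):
            PukParams(sigma=-1.0)


class TestGramMatrix:
    def test_single_row(self):
        assert gram_matrix(np.array([[1.0, 2.0]])) == pytest.approx(np.array([[1.0]]))

    def test_duplicated_rows(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]])
        K = gram_matrix(X)
        assert K[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(K), 1.0)
        assert np.allclose(K, K.T)

    def test_positive_semidefinite_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            X = rng.standard_normal((20, 5))
            params = PukParams(omega=rng.uniform(0.5, 3.0), sigma=rng.uniform(0.5, 3.0))
            K = gram_matrix(X, params)
            assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestTrainPredict:
    def test_constant_target_inside_tube(self):
        X = np.linspace(0, 1, 6)[:, None]
        m = train_svr(X, np.full(6, 2.5), PukParams(), SVRParams(cost=1.0, epsilon_tube=0.01))
        assert m.dual_coefficients.size == 0
        assert m.bias == pytest.approx(2.5)
        assert np.allclose(predict(m, X), 2.5)

    def test_line_fit_residuals(self):
        X = np.linspace(0, 1, 6)[:, None]
        y = X.ravel()
        m = train_svr(X, y, PukParams(), SVRParams(cost=100.0, epsilon_tube=0.001))
        assert np.abs(predict(m, X) - y).max() <= 0.05

    def test_conflicting_duplicates_average(self):
        X = np.array([[0.0], [0.0], [1.0]])
        y = np.array([0.0, 1.0, 0.5])
        m = train_svr(X, y, PukParams(), SVRParams(cost=10.0))
        pred = predict(m, np.array([[0.0]]))[0]
        assert 0.0 < pred < 1.0

    def test_box_constraints_and_kkt(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 4))
        y = X[:, 0] * 0.5 + rng.normal(0, 0.1, 30)
        svr = SVRParams(cost=5.0, epsilon_tube=0.05)
        m = train_svr(X, y, PukParams(1.0, 3.0), svr)
        assert np.all(np.abs(m.dual_coefficients) <= svr.cost + 1e-9)
        # free support vectors (|alpha| < C) must sit on the tube boundary
        sv_idx = [int(np.where((X == sv).all(axis=1))[0][0]) for sv in m.support_vectors]
        yhat = predict(m, m.support_vectors)
        free = np.abs(m.dual_coefficients) < svr.cost - 1e-6
        residuals = np.abs(yhat - y[sv_idx])
        assert np.all(residuals[free] <= svr.epsilon_tube + 1e-2)

    def test_nonfinite_rejected(self):
        X = np.array([[0.0], [np.nan]])
        with pytest.raises(ValueError, match="non-finite"):
            train_svr(X, np.array([0.0, 1.0]))

    def test_prediction_order_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        m = train_svr(X, y, PukParams(1.0, 2.0), SVRParams(cost=2.0))
        Q = rng.standard_normal((7, 3))
        direct = predict(m, Q)
        reversed_ = predict(m, Q[::-1])[::-1]
        assert np.allclose(direct, reversed_)

    def test_predict_dimension_mismatch(self):
        X = np.zeros((3, 2))
        m = train_svr(X + np.arange(3)[:, None], np.array([0.0, 1.0, 2.0]))
        with pytest.raises(ValueError, match="dimension"):
            predict(m, np.zeros((2, 5)))

    def test_deterministic_training(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((25, 4))
        y = rng.standard_normal(25)
        m1 = train_svr(X, y, PukParams(1.0, 2.0), SVRParams(cost=3.0))
        m2 = train_svr(X, y, PukParams(1.0, 2.0), SVRParams(cost=3.0))
        assert np.array_equal(m1.dual_coefficients, m2.dual_coefficients)
        assert m1.bias == m2.bias

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((15, 3))
        y = rng.standard_normal(15)
        m = train_svr(X, y, PukParams(1.3, 2.2), SVRParams(cost=4.0))
        path = tmp_path / "model.npz"
        m.save(path)
        loaded = TrainedPCMModel.load(path)
        Q = rng.standard_normal((5, 3))
        assert np.allclose(predict(m, Q), predict(loaded, Q))
        assert loaded.puk == m.puk and loaded.svr.cost == m.svr.cost


class TestQSquared:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert q_squared(y, y, y_ref_mean=2.0) == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert q_squared(y, np.full(3, 2.0), y_ref_mean=2.0) == pytest.approx(0.0)

    def test_hand_example(self):
        assert q_squared([1, 2, 3], [1, 2, 4], y_ref_mean=2.0) == pytest.approx(0.5)

    def test_degenerate_reference(self):
        with pytest.raises(ValueError, match="degenerate"):
            q_squared([2.0, 2.0], [1.0, 3.0], y_ref_mean=2.0)


class TestCrossValidation:
    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (40, 1))
        y = X.ravel()
        q2 = cross_validate(X, y, PukParams(1.0, 2.0), SVRParams(cost=100.0), k=10, seed=0)
        assert q2 >= 0.99

    def test_pure_noise_has_no_skill(self):
        vals = []
        for s in range(10):
            rng = np.random.default_rng(s)
            X = rng.standard_normal((40, 5))
            y = rng.standard_normal(40)
            vals.append(cross_validate(X, y, PukParams(1.0, 2.0),
                                       SVRParams(cost=10.0), k=5, seed=s))
        assert np.mean(vals) <= 0.1

    def test_leave_one_out_runs(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((8, 2))
        y = rng.standard_normal(8)
        assert np.isfinite(cross_validate(X, y, k=8, seed=0))

    def test_k_out_of_range(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            cross_validate(X, np.zeros(5), k=6)
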