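"""Feedforward network, analytic Jacobian and Levenberg-Marquardt trainer."""

import numpy as np
import pytest

from fingercoord import network
from fingercoord.kinematics import JointAngleSeries
from fingercoord.network import (
    FeatureMatrix,
    NetworkParams,
    TrainConfig,
    build_features,
    denormalize,
    feature_ranges,
    flatten,
    forward,
    init_params,
    normalize,
    param_count,
    residual_jacobian,
    train_lm,
    unflatten,
)


def _series(n: int) -> JointAngleSeries:
    t = np.arange(n) * 0.01
    return JointAngleSeries(
        time_s=t,
        theta1_deg=10 + np.sin(t),
        omega1_deg_s=np.cos(t),
        alpha1_deg_s2=-np.sin(t),
        beta1_deg=8 + 0.8 * np.sin(t),
    )


class TestFeatures:
    def test_individual_mode_has_three_columns(self):
        fm = build_features(_series(50), mode="individual")
        assert fm.X.shape == (50, 3)
        assert fm.column_names == ["theta1_deg", "omega1_deg_s", "alpha1_deg_s2"]

    def test_multi_mode_appends_constant_covariates(self, subject):
        fm = build_features(_series(20), subject, mode="multi")
        assert fm.X.shape == (20, 6)
        np.testing.assert_array_equal(fm.X[:, 3], 80.3)  # ring length
        np.testing.assert_array_equal(fm.X[:, 4], 84.8)  # middle length

    def test_multi_mode_requires_profile(self):
        with pytest.raises(ValueError):
            build_features(_series(5), None, mode="multi")

    def test_empty_series_gives_empty_matrix(self):
        fm = build_features(_series(0), mode="individual")
        assert fm.X.shape == (0, 3)


class TestNormalization:
    def test_training_min_maps_to_minus_one_and_midpoint_to_zero(self):
        X = np.array([[0.0], [5.0], [10.0]])
        lo, hi = feature_ranges(X)
        Xn = normalize(X, lo, hi)
        np.testing.assert_allclose(Xn[:, 0], [-1.0, 0.0, 1.0])

    def test_round_trip_identity(self, rng):
        X = rng.normal(size=(40, 4)) * 30
        lo, hi = feature_ranges(X)
        np.testing.assert_allclose(
            denormalize(normalize(X, lo, hi), lo, hi), X, atol=1e-12
        )

    def test_degenerate_column_named_in_error(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        with pytest.raises(ValueError, match="const"):
            feature_ranges(X, ["a", "const"])


class TestForwardAndFlatten:
    def test_zero_weights_output_bias(self):
        p = NetworkParams(W1=np.zeros((13, 3)), b1=np.zeros(13),
                          W2=np.zeros(13), b2=5.0)
        np.testing.assert_array_equal(forward(p, np.ones((4, 3))), 5.0)

    def test_single_unit_tanh_by_hand(self):
        p = NetworkParams(W1=np.ones((1, 1)), b1=np.zeros(1),
                          W2=np.ones(1), b2=0.0)
        assert forward(p, [[0.5]])[0] == pytest.approx(0.46212, abs=1e-5)

    def test_hidden_unit_permutation_invariance(self, rng):
        p = init_params(3, 13, rng=rng)
        X = rng.normal(size=(10, 3))
        perm = rng.permutation(13)
        q = NetworkParams(W1=p.W1[perm], b1=p.b1[perm], W2=p.W2[perm], b2=p.b2)
        np.testing.assert_allclose(forward(p, X), forward(q, X), atol=1e-12)

    def test_tanh_sign_flip_invariance(self, rng):
        p = init_params(2, 5, rng=rng)
        X = rng.normal(size=(10, 2))
        q = NetworkParams(W1=-p.W1, b1=-p.b1, W2=-p.W2, b2=p.b2)
        np.testing.assert_allclose(forward(p, X), forward(q, X), atol=1e-12)

    @pytest.mark.parametrize("d, expected", [(3, 66), (6, 105)])
    def test_flattened_length(self, d, expected):
        assert param_count(d) == expected
        assert flatten(init_params(d, rng=0)).size == expected

    def test_flatten_unflatten_round_trip(self, rng):
        p = init_params(6, 13, rng=rng)
        q = unflatten(flatten(p), 6, 13)
        np.testing.assert_array_equal(flatten(p), flatten(q))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            unflatten(np.zeros(10), 3, 13)


class TestJacobian:
    @pytest.mark.parametrize("d, h, seed", [(2, 3, 0), (3, 5, 1), (6, 4, 2)])
    def test_analytic_matches_central_differences(self, d, h, seed):
        rng = np.random.default_rng(seed)
        p = init_params(d, h, rng=rng, scale=1.0)
        X = rng.normal(size=(9, d))
        J = residual_jacobian(p, X)
        theta = flatten(p)
        Jn = np.empty_like(J)
        eps = 1e-6
        for j in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += eps
            tm[j] -= eps
            Jn[:, j] = (
                forward(unflatten(tp, d, h), X)
                - forward(unflatten(tm, d, h), X)
            ) / (2 * eps)
        assert np.abs(J - Jn).max() / np.abs(Jn).max() < 1e-5

    def test_mse_gradient_matches_finite_differences(self, rng):
        d, h = 3, 4
        p = init_params(d, h, rng=rng)
        X = rng.normal(size=(20, d))
        y = rng.normal(size=20)
        J = residual_jacobian(p, X)
        r = forward(p, X) - y
        grad = 2.0 * (J.T @ r) / X.shape[0]
        theta = flatten(p)
        eps = 1e-6

        def mse(v):
            rr = forward(unflatten(v, d, h), X) - y
            return np.mean(rr * rr)

        for j in range(0, theta.size, 7):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += eps
            tm[j] -= eps
            assert grad[j] == pytest.approx(
                (mse(tp) - mse(tm)) / (2 * eps), rel=1e-4, abs=1e-8
            )


class TestTrainLM:
    def test_zero_epochs_returns_params_unchanged(self, rng):
        p = init_params(1, 3, rng=rng)
        X = rng.normal(size=(10, 1))
        y = rng.normal(size=10)
        trained, history = train_lm(p, X, y, TrainConfig(max_epochs=0))
        np.testing.assert_array_equal(flatten(trained), flatten(p))
        assert len(history) == 1

    def test_recovers_linear_target(self):
        X = np.linspace(-1, 1, 50)[:, None]
        y = 2 * X[:, 0] + 1
        p = init_params(1, 13, rng=0)
        trained, history = train_lm(p, X, y, TrainConfig(max_epochs=200))
        assert history[-1] < 1e-6

    def test_fits_sine_with_13_hidden_units(self):
        X = np.linspace(-np.pi, np.pi, 200)[:, None]
        y = np.sin(X[:, 0])
        p = init_params(1, 13, rng=1)
        trained, history = train_lm(p, X, y, TrainConfig(max_epochs=300))
        assert history[-1] < 1e-3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_accepted_loss_history_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(60, 2))
        y = np.tanh(X[:, 0]) - 0.5 * X[:, 1] + rng.normal(0, 0.1, 60)
        p = init_params(2, 6, rng=seed)
        _, history = train_lm(p, X, y, TrainConfig(max_epochs=80))
        assert all(b <= a for a, b in zip(history, history[1:]))

    def test_sgd_variant_reduces_loss(self, rng):
        X = rng.uniform(-1, 1, size=(200, 1))
        y = 0.5 * X[:, 0]
        p = init_params(1, 13, rng=3)
        cfg = TrainConfig(max_epochs=30, method="sgd", seed=5)
        _, history = train_lm(p, X, y, cfg)
        assert history[-1] < history[0]


class TestSerialization:
    def test_model_round_trip(self, tmp_path, rng):
        p = init_params(6, 13, rng=rng)
        ranges = {"x_min": np.zeros(6), "x_max": np.ones(6),
                  "y_min": [0.0], "y_max": [50.0]}
        path = tmp_path / "model.json"
        network.save_model(path, p, ranges, {"seed": 4})
        q, r, meta = network.load_model(path)
        np.testing.assert_array_equal(flatten(p), flatten(q))
        np.testing.assert_array_equal(r["x_max"], ranges["x_max"])
        assert meta["seed"] == 4
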