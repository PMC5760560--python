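"""MLP tests: forward pass against hand evaluation, backprop against a
central finite-difference oracle, training-loop contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from musemo import mlp


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _loss(net, X, Y):
    """Total loss the summed update descends: sum_i (1/2)(y_i - t_i)^2."""
    y = mlp.forward(net, X)
    return 0.5 * float(np.sum((y - np.asarray(Y).ravel()) ** 2))


def _fd_gradients(net, X, Y, eps=1e-6):
    """Central finite differences of the total loss w.r.t. every weight."""
    def perturb(attr, idx, delta):
        n = net.copy()
        arr = getattr(n, attr)
        if attr == "b_o":
            n.b_o = n.b_o + delta
        else:
            arr = arr.copy()
            arr[idx] += delta
            setattr(n, attr, arr)
        return n

    grads = {}
    for attr in ("w_hi", "w_oh"):
        arr = getattr(net, attr)
        g = np.zeros_like(arr)
        for idx in np.ndindex(arr.shape):
            g[idx] = (_loss(perturb(attr, idx, eps), X, Y)
                      - _loss(perturb(attr, idx, -eps), X, Y)) / (2 * eps)
        grads[attr] = g
    if net.b_h is not None:
        g = np.zeros_like(net.b_h)
        for idx in np.ndindex(net.b_h.shape):
            g[idx] = (_loss(perturb("b_h", idx, eps), X, Y)
                      - _loss(perturb("b_h", idx, -eps), X, Y)) / (2 * eps)
        grads["b_h"] = g
        grads["b_o"] = (_loss(perturb("b_o", None, eps), X, Y)
                        - _loss(perturb("b_o", None, -eps), X, Y)) / (2 * eps)
    return grads


def gradient_check(seed, use_bias=True):
    rng = np.random.default_rng(seed)
    n_in = int(rng.integers(2, 8))
    n_hidden = int(rng.integers(1, 5))
    n = int(rng.integers(2, 10))
    cfg = mlp.TrainingConfig(use_bias=use_bias, init_half_range=0.5, seed=seed)
    net = mlp.init_network(n_in, n_hidden, cfg, rng=rng)
    X = rng.uniform(0, 1, size=(n, n_in))
    Y = rng.uniform(0.1, 0.9, size=n)
    g_w_hi, g_w_oh, g_b_h, g_b_o, _ = mlp.gradients(net, X, Y)
    fd = _fd_gradients(net, X, Y)

    def rel_err(a, b):
        return np.abs(a - b) / np.maximum(np.maximum(np.abs(a), np.abs(b)), 1e-4)

    assert rel_err(g_w_hi, fd["w_hi"]).max() <= 1e-5
    assert rel_err(g_w_oh, fd["w_oh"]).max() <= 1e-5
    if use_bias:
        assert rel_err(g_b_h, fd["b_h"]).max() <= 1e-5
        assert rel_err(np.array(g_b_o), np.array(fd["b_o"])).max() <= 1e-5


class TestInit:
    def test_shapes_for_study_architectures(self):
        cfg = mlp.TrainingConfig(seed=0)
        net10 = mlp.init_network(10, 3, cfg)
        assert net10.w_hi.shape == (3, 10) and net10.w_oh.shape == (3,)
        net5 = mlp.init_network(5, 3, cfg)
        assert net5.w_hi.shape == (3, 5)

    def test_init_range_and_determinism(self):
        cfg = mlp.TrainingConfig(seed=9)
        net = mlp.init_network(10, 3, cfg)
        for arr in (net.w_hi, net.w_oh, net.b_h, np.array([net.b_o])):
            assert (np.abs(arr) < 0.05).all()
        again = mlp.init_network(10, 3, cfg)
        np.testing.assert_array_equal(net.w_hi, again.w_hi)


class TestForward:
    def test_zero_weights_give_half(self):
        net = mlp.NetworkWeights(np.zeros((3, 4)), np.zeros(3), np.zeros(3), 0.0)
        assert mlp.forward(net, np.zeros((1, 4)))[0] == pytest.approx(0.5)

    def test_hand_evaluated_chain(self):
        """2-2-1 net, identity-like weights, no bias: y = sigmoid(1.0)."""
        net = mlp.NetworkWeights(np.eye(2), np.array([1.0, 1.0]), None, None)
        y = mlp.forward(net, np.array([[0.0, 0.0]]))[0]
        assert y == pytest.approx(_sigmoid(_sigmoid(0) + _sigmoid(0)), abs=1e-12)
        assert y == pytest.approx(0.7311, abs=1e-4)

    def test_output_strictly_in_unit_interval(self):
        rng = np.random.default_rng(0)
        cfg = mlp.TrainingConfig(seed=0, init_half_range=2.0)
        net = mlp.init_network(6, 3, cfg, rng=rng)
        y = mlp.forward(net, rng.uniform(-5, 5, size=(50, 6)))
        assert ((y > 0) & (y < 1)).all()

    def test_dimension_mismatch(self):
        net = mlp.init_network(4, 2, mlp.TrainingConfig(seed=0))
        with pytest.raises(ValueError, match="features"):
            mlp.forward(net, np.zeros((1, 5)))


class TestBackprop:
    @pytest.mark.parametrize("seed", range(100))
    def test_gradient_matches_finite_differences(self, seed):
        gradient_check(seed, use_bias=True)

    @pytest.mark.parametrize("seed", range(10))
    def test_gradient_matches_finite_differences_no_bias(self, seed):
        gradient_check(seed, use_bias=False)

    def test_zero_learning_rate_leaves_weights(self):
        rng = np.random.default_rng(1)
        cfg = mlp.TrainingConfig(seed=1)
        net = mlp.init_network(4, 3, cfg)
        X, Y = rng.uniform(0, 1, (8, 4)), rng.uniform(0, 1, 8)
        frozen = mlp.TrainingConfig(learning_rate=1e-300, seed=1)
        new, mse1 = mlp.backprop_epoch(net, X, Y, frozen)
        np.testing.assert_allclose(new.w_hi, net.w_hi, atol=1e-290)
        _, mse2 = mlp.backprop_epoch(new, X, Y, frozen)
        assert mse1 == pytest.approx(mse2, abs=1e-12)

    def test_presentation_order_does_not_affect_update(self):
        rng = np.random.default_rng(2)
        cfg = mlp.TrainingConfig(seed=2)
        net = mlp.init_network(5, 3, cfg)
        X, Y = rng.uniform(0, 1, (12, 5)), rng.uniform(0, 1, 12)
        a, _ = mlp.backprop_epoch(net, X, Y, cfg, rng=np.random.default_rng(10))
        b, _ = mlp.backprop_epoch(net, X, Y, cfg, rng=np.random.default_rng(99))
        np.testing.assert_allclose(a.w_hi, b.w_hi, atol=1e-10)
        np.testing.assert_allclose(a.w_oh, b.w_oh, atol=1e-10)


class TestTrain:
    def test_learnable_target_converges_below_threshold(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, size=(36, 4))
        Y = _sigmoid(6.0 * X[:, 0] - 4.0 * X[:, 1] - 1.0)
        model = mlp.train(X, Y, mlp.TrainingConfig(seed=3, max_epochs=5000))
        assert model.trace.converged
        assert np.mean((model.predict(X) - Y) ** 2) < 0.045
        assert model.trace.epochs_run > 0

    def test_zero_epochs_returns_initial_weights(self):
        rng = np.random.default_rng(4)
        X, Y = rng.uniform(0, 1, (10, 3)), rng.uniform(0.3, 0.7, 10)
        cfg = mlp.TrainingConfig(seed=4, max_epochs=0, target_mse=1e-6)
        with pytest.warns(UserWarning, match="did not reach"):
            model = mlp.train(X, Y, cfg)
        assert not model.trace.converged
        assert model.trace.epochs_run == 0
        expected = mlp.init_network(3, 3, cfg, rng=np.random.default_rng(4))
        np.testing.assert_array_equal(model.weights.w_hi, expected.w_hi)

    def test_training_reduces_mse(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, size=(36, 6))
        Y = _sigmoid(X @ rng.uniform(-1, 1, 6))
        cfg = mlp.TrainingConfig(seed=5, max_epochs=2000, target_mse=1e-9)
        with pytest.warns(UserWarning):
            model = mlp.train(X, Y, cfg)
        assert model.trace.mse[-1] <= model.trace.mse[0]

    def test_separate_dimension_interface(self):
        """A network is bound to one dimension; it never sees the other's
        targets (single target vector in, dimension tag recorded)."""
        rng = np.random.default_rng(6)
        X, Y = rng.uniform(0, 1, (10, 3)), rng.uniform(0, 1, 10)
        model = mlp.train(X, Y, mlp.TrainingConfig(seed=6, max_epochs=10,
                                                   target_mse=0.9),
                          dimension="valence")
        assert model.dimension == "valence"

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        X, Y = rng.uniform(0, 1, (10, 3)), rng.uniform(0.4, 0.6, 10)
        model = mlp.train(X, Y, mlp.TrainingConfig(seed=7, max_epochs=50),
                          feature_names=["a", "b", "c"], dimension="arousal")
        model.save(tmp_path / "net.json")
        again = mlp.NetworkModel.load(tmp_path / "net.json")
        np.testing.assert_array_equal(again.weights.w_hi, model.weights.w_hi)
        x = rng.uniform(0, 1, (4, 3))
        np.testing.assert_allclose(again.predict(x), model.predict(x), atol=0)


class TestRmse:
    def test_values(self):
        assert mlp.rmse([1, 1], [1, 1]) == 0.0
        assert mlp.rmse([0, 1], [1, 1]) == pytest.approx(np.sqrt(0.5))

    @given(st.floats(min_value=-10, max_value=10, allow_nan=False),
           st.integers(min_value=1, max_value=20))
    @settings(max_examples=30, deadline=None)
    def test_scale_equivariance(self, a, n):
        rng = np.random.default_rng(abs(hash((round(a, 3), n))) % 2**31)
        p, t = rng.standard_normal(n), rng.standard_normal(n)
        assert mlp.rmse(a * p, a * t) == pytest.approx(abs(a) * mlp.rmse(p, t),
                                                       rel=1e-9, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mlp.rmse([], [])
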