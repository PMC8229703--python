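"""Forward pass, backpropagation, clipping, and offline training of the jump network."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import glyjump as gj
from glyjump.jumpnet import JumpNetGrads

from conftest import START


def _flatten(obj):
    return np.concatenate([
        obj.IHW.ravel(), obj.HOW, obj.IOW, obj.hidden_bias, [obj.output_bias]
    ])


def _perturbed(params, delta):
    L, M = params.L, params.M
    i = 0
    out = params.copy()
    out.IHW = out.IHW + delta[i : i + L * M].reshape(L, M); i += L * M
    out.HOW = out.HOW + delta[i : i + L]; i += L
    out.IOW = out.IOW + delta[i : i + M]; i += M
    out.hidden_bias = out.hidden_bias + delta[i : i + L]; i += L
    out.output_bias = out.output_bias + float(delta[i])
    return out


def _loop_forward(params, x):
    """Per-neuron scalar-product oracle for the jump equation."""
    linear = sum(params.IOW[j] * x[j] for j in range(params.M))
    nonlinear = 0.0
    for ell in range(params.L):
        z = sum(params.IHW[ell, j] * x[j] for j in range(params.M))
        nonlinear += params.HOW[ell] * np.tanh(z + params.hidden_bias[ell])
    return linear + nonlinear + params.output_bias


def _dataset(X, y, start=START):
    n = X.shape[0]
    times = pd.date_range(start, periods=n, freq="min")
    return gj.WindowedDataset(
        inputs=np.asarray(X, float), targets=np.asarray(y, float),
        anchor_times=times, target_times=times + pd.Timedelta(minutes=30),
        series_start=start,
    )


class TestInit:
    def test_seed_determinism(self):
        a, b = gj.init_params(10, 4, seed=7), gj.init_params(10, 4, seed=7)
        np.testing.assert_array_equal(_flatten(a), _flatten(b))

    def test_glorot_bounds_and_zero_biases(self):
        p = gj.init_params(10, 4, seed=0)
        assert np.all(np.abs(p.IHW) <= np.sqrt(6 / 14))
        assert np.all(np.abs(p.HOW) <= np.sqrt(6 / 5))
        assert np.all(np.abs(p.IOW) <= np.sqrt(6 / 11))
        assert not p.hidden_bias.any() and p.output_bias == 0.0

    def test_different_seeds_differ(self):
        assert (_flatten(gj.init_params(10, 4, 1)) != _flatten(gj.init_params(10, 4, 2))).any()


class TestForward:
    def test_zero_network_outputs_zero(self):
        p = gj.JumpNetParams(np.zeros((4, 10)), np.zeros(4), np.zeros(10), np.zeros(4))
        assert gj.forward(p, np.full(10, 150.0)) == 0.0

    def test_jump_path_isolates_last_input(self):
        iow = np.zeros(10); iow[-1] = 1.0
        p = gj.JumpNetParams(np.random.default_rng(0).normal(size=(4, 10)),
                             np.zeros(4), iow, np.zeros(4))
        x = np.linspace(90, 137, 10)
        assert gj.forward(p, x) == pytest.approx(137.0)

    def test_matches_per_neuron_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p = gj.init_params(10, 4, seed=int(rng.integers(1 << 30)))
            p.hidden_bias = rng.normal(size=4)
            p.output_bias = float(rng.normal())
            x = rng.uniform(40, 400, 10)
            assert gj.forward(p, x) == pytest.approx(_loop_forward(p, x), abs=1e-12, rel=1e-12)

    def test_batch_equals_rowwise(self):
        p = gj.init_params(10, 4, 5)
        X = np.random.default_rng(5).uniform(80, 200, (7, 10))
        np.testing.assert_allclose(gj.forward(p, X), [gj.forward(p, x) for x in X])

    def test_wrong_window_length_raises(self):
        with pytest.raises(ValueError, match="M=10"):
            gj.forward(gj.init_params(10, 4, 0), np.ones(9))


class TestGradients:
    def test_zero_sample_weights_give_zero_gradients(self):
        p = gj.init_params(10, 4, 1)
        X = np.random.default_rng(1).uniform(80, 200, (5, 10))
        g = gj.weighted_sse_gradients(p, X, np.full(5, 120.0), np.zeros(5))
        assert not _flatten(g).any()

    def test_unit_weights_equal_plain_mse_gradient(self):
        p = gj.init_params(10, 4, 2)
        X = np.random.default_rng(2).uniform(80, 200, (6, 10))
        y = np.random.default_rng(3).uniform(80, 200, 6)
        a = gj.weighted_sse_gradients(p, X, y, np.ones(6))
        b = gj.weighted_sse_gradients(p, X, y, None)
        np.testing.assert_array_equal(_flatten(a), _flatten(b))

    @pytest.mark.parametrize("loss", ["mse", "penalized"])
    @pytest.mark.parametrize("biases", [False, True])
    def test_finite_difference_agreement(self, loss, biases):
        rng = np.random.default_rng(17)
        for _ in range(20):
            p = gj.init_params(6, 3, seed=int(rng.integers(1 << 30)))
            p.biases_enabled = biases
            if biases:
                p.hidden_bias = rng.normal(size=3) * 0.1
                p.output_bias = float(rng.normal())
            X = rng.uniform(-2, 2, (4, 6))
            y = rng.uniform(-2, 2, 4)
            e = y - gj.forward(p, X)
            w = gj.penalty(e) if loss == "penalized" else np.ones(4)
            analytic = _flatten(gj.weighted_sse_gradients(p, X, y, w))
            n_par = analytic.size

            def f(theta_delta):
                q = _perturbed(p, theta_delta)
                r = y - gj.forward(q, X)
                return np.mean(w * r * r)

            fd = np.empty(n_par)
            h = 1e-6
            for k in range(n_par):
                d = np.zeros(n_par); d[k] = h
                fd[k] = (f(d) - f(-d)) / (2 * h)
            live = ~np.isclose(fd, 0, atol=1e-9)
            if not biases:
                # disabled biases report zero gradient by contract
                assert not analytic[-4:].any()
                live[-4:] = False
            np.testing.assert_allclose(analytic[live], fd[live], rtol=1e-4)


class TestClipAndStep:
    @pytest.mark.parametrize("value, expected", [(0.7, 0.3), (-0.1, -0.1), (0.3, 0.3)])
    def test_clip_scalar_cases(self, value, expected):
        g = JumpNetGrads(np.full((1, 1), value), np.zeros(1), np.zeros(1), np.zeros(1), 0.0)
        assert gj.clip_gradients(g, 0.3).IHW[0, 0] == pytest.approx(expected)

    def test_clip_vector_elementwise(self):
        g = JumpNetGrads(np.zeros((1, 3)), np.zeros(1), np.array([-1.0, 0.0, 1.0]), np.zeros(1), 0.0)
        np.testing.assert_allclose(gj.clip_gradients(g, 0.3).IOW, [-0.3, 0.0, 0.3])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=8),
           st.floats(1e-3, 10.0))
    def test_clipping_never_increases_magnitude(self, comps, clip):
        arr = np.array(comps)
        g = JumpNetGrads(arr.reshape(1, -1), np.zeros(1), np.zeros(arr.size), np.zeros(1), 0.0)
        clipped = gj.clip_gradients(g, clip).IHW.ravel()
        assert np.all(np.abs(clipped) <= np.minimum(np.abs(arr), clip) + 1e-15)

    def test_sgd_step_arithmetic(self):
        p = gj.JumpNetParams(np.ones((1, 1)), np.zeros(1), np.zeros(1), np.zeros(1))
        g = JumpNetGrads(np.full((1, 1), 0.5), np.zeros(1), np.zeros(1), np.zeros(1), 0.0)
        assert gj.sgd_step(p, g, 0.1).IHW[0, 0] == pytest.approx(0.95)
        assert gj.sgd_step(p, g, 0.0).IHW[0, 0] == 1.0
        zero = JumpNetGrads(np.zeros((1, 1)), np.zeros(1), np.zeros(1), np.zeros(1), 0.0)
        assert gj.sgd_step(p, zero, 0.1).IHW[0, 0] == 1.0


class TestTrainOffline:
    def test_linear_target_recovery(self):
        # HOW = IHW = 0 keeps the model exactly linear throughout training:
        # tanh(0) = 0 zeroes the hidden-path gradients.
        rng = np.random.default_rng(0)
        M = 10
        iow_true = rng.uniform(-0.5, 0.5, M)
        X = rng.normal(size=(1200, M))
        y = X @ iow_true
        train, val = _dataset(X[:1000], y[:1000]), _dataset(X[1000:], y[1000:])
        p = gj.init_params(M, 4, seed=1)
        p.HOW[:] = 0.0
        p.IHW[:] = 0.0
        hyper = gj.TrainingHyperparams(learning_rate=0.1, max_epochs=500, clip_value=0.3,
                                       validation_check_every=4, patience_checks=10, seed=1)
        best, _ = gj.train_offline(p, train, val, hyper)
        assert not best.HOW.any() and not best.IHW.any()
        np.testing.assert_allclose(best.IOW, iow_true, atol=0.05)
        resid = train.targets - gj.forward(best, train.inputs)
        assert gj.rmse(resid) < 1.0

    def test_early_stopping_returns_best_check_params(self):
        # train pulls IOW[0] upward forever; validation wants it where it started,
        # so every check after the first is strictly worse
        X_tr = np.zeros((4, 3)); X_tr[:, 0] = 1.0
        y_tr = np.full(4, 1000.0)
        X_va = X_tr.copy()
        p = gj.JumpNetParams(np.zeros((2, 3)), np.zeros(2), np.zeros(3), np.zeros(2))
        y_va = np.zeros(4)     # best at initial IOW[0] = 0, worsens monotonically
        hyper = gj.TrainingHyperparams(learning_rate=0.1, max_epochs=100, clip_value=0.3,
                                       validation_check_every=1, patience_checks=1)
        best, hist = gj.train_offline(p, _dataset(X_tr, y_tr), _dataset(X_va, y_va), hyper)
        assert len(hist["val_checks"]) == 2            # stops after the 2nd check
        assert hist["best_epoch"] == 1
        assert best.IOW[0] == pytest.approx(0.03)      # value after epoch 1 (clip 0.3 * lr 0.1)

    def test_zero_max_epochs_rejected(self):
        p = gj.init_params(3, 2, 0)
        d = _dataset(np.ones((4, 3)), np.ones(4))
        hyper = gj.TrainingHyperparams(learning_rate=0.1, max_epochs=0)
        with pytest.raises(ValueError, match="max_epochs"):
            gj.train_offline(p, d, d, hyper)

    def test_training_is_bitwise_reproducible(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(80, 200, (60, 5)); y = rng.uniform(80, 200, 60)
        d_tr, d_va = _dataset(X[:40], y[:40]), _dataset(X[40:], y[40:])
        hyper = gj.TrainingHyperparams(learning_rate=0.01, max_epochs=30, batch_size=16, seed=4)
        out = [gj.train_offline(gj.init_params(5, 4, 4), d_tr, d_va, hyper)[0] for _ in range(2)]
        np.testing.assert_array_equal(_flatten(out[0]), _flatten(out[1]))

    def test_divergence_reported_with_epoch(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(80, 200, (40, 5)); y = rng.uniform(80, 200, 40)
        d = _dataset(X, y)
        hyper = gj.TrainingHyperparams(learning_rate=1e12, max_epochs=50, clip_value=None)
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(gj.TrainingDivergedError, match="epoch"):
                gj.train_offline(gj.init_params(5, 4, 2), d, d, hyper)

    def test_checkpoint_json_round_trip(self, tmp_path):
        p = gj.init_params(10, 4, 3)
        p.to_json(tmp_path / "params.json")
        q = gj.JumpNetParams.from_json(tmp_path / "params.json")
        np.testing.assert_array_equal(_flatten(p), _flatten(q))
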