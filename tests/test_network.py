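"""Network architecture, curve-difference loss, and the training protocol."""

import math

import numpy as np
import pytest

from gcresponse import (
    NetworkSpec,
    TrainConfig,
    TrainedModel,
    build_network,
    curve_difference_loss,
    curve_from_params,
)
from gcresponse.encoding import EncodedTree, InputScaler
from gcresponse.network import (
    TrainHistory,
    _sigmoid_head_loss_grad,
    affinity_grid,
    train,
)


class TestCurveDifferenceLoss:
    def test_identity_is_zero(self):
        g = affinity_grid()
        c = curve_from_params(np.array([1.6, 2.0, 18.2, 0.4]), g)
        assert curve_difference_loss(c, c, g) == 0.0

    def test_flat_curves_half(self):
        # true = 2, inferred = 3 on [-2.5, 3]: (5.5 * 1) / (5.5 * 2) = 0.5
        g = affinity_grid()
        assert curve_difference_loss(np.full_like(g, 2.0), np.full_like(g, 3.0), g) == (
            pytest.approx(0.5)
        )

    def test_numerator_symmetry(self):
        g = affinity_grid()
        a = curve_from_params(np.array([1.0, 0.5, 10.0, 0.2]), g)
        b = curve_from_params(np.array([0.5, 1.5, 20.0, 0.1]), g)
        area_a = np.trapezoid(a, g)
        area_b = np.trapezoid(b, g)
        assert curve_difference_loss(a, b, g) * area_a == pytest.approx(
            curve_difference_loss(b, a, g) * area_b
        )

    def test_nonnegative_and_zero_only_on_equality(self):
        g = affinity_grid()
        a = curve_from_params(np.array([1.0, 0.5, 10.0, 0.2]), g)
        b = a.copy()
        b[3] += 1e-3
        assert curve_difference_loss(a, b, g) > 0

    def test_zero_area_rejected(self):
        g = affinity_grid()
        with pytest.raises(ValueError):
            curve_difference_loss(np.zeros_like(g), np.ones_like(g), g)

    def test_parameter_compensation(self):
        # very different parameter vectors, nearly identical curve shapes:
        # doubling/tripling y_c while shifting x_h by log(k)/x_c leaves the
        # visible (left) flank of an off-domain sigmoid almost unchanged
        g = affinity_grid()
        p1 = np.array([2.0, 4.5, 20.0, 0.2])
        p2 = np.array([2.0, 4.5 + math.log(3) / 2.0, 60.0, 0.2])
        assert np.linalg.norm(p1 - p2) > 10
        loss = curve_difference_loss(curve_from_params(p1, g), curve_from_params(p2, g), g)
        assert loss < 0.05


class TestArchitecture:
    def test_layer_parameter_counts(self):
        net = build_network(NetworkSpec())
        counts = net.layer_param_counts()
        assert counts["conv2"] == 2525
        assert counts["conv3"] == 4040
        assert counts["dense2"] == 1568
        assert counts["dense3"] == 528
        assert counts["dense4"] == 136

    def test_sigmoid_head_outputs_four(self):
        net = build_network(NetworkSpec())
        out = net.predict(np.zeros((4, 200)), np.zeros(3))
        assert out.shape == (1, 4)

    def test_per_bin_head_outputs_bins(self):
        spec = NetworkSpec(head="per_bin", n_bins=11)
        net = build_network(spec)
        out = net.predict(np.zeros((4, 200)), np.zeros(3))
        assert out.shape == (1, 11)
        assert len(spec.bin_grid()) == 11
        assert spec.bin_grid()[0] == pytest.approx(-2.5 + 5.5 / 22)

    def test_outputs_respect_clip_bounds(self):
        net = build_network(NetworkSpec(), seed=0)
        rng = np.random.default_rng(1)
        X = rng.standard_normal((16, 4, 200)) * 10
        Z = rng.standard_normal((16, 3)) * 10
        out = net.forward(X, Z)
        lo, hi = net.spec.output_clip()
        assert np.all(out >= lo) and np.all(out <= hi)

    def test_gradients_match_numerical(self):
        net = build_network(NetworkSpec(), seed=2)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((2, 4, 200)) * 0.5
        Z = rng.standard_normal((2, 3))
        truth = np.array([[1.0, 0.5, 10.0, 0.2], [1.5, 1.0, 20.0, 0.4]])
        g = affinity_grid()
        cache = {}
        out = net.forward(X, Z, cache)
        _, dout = _sigmoid_head_loss_grad(out, truth, g)
        grads = net.backward(cache, dout)

        def loss_now():
            o = net.forward(X, Z)
            ls, _ = _sigmoid_head_loss_grad(o, truth, g)
            return ls.mean()

        eps = 1e-6
        for key in ("conv1_w", "conv2_w", "conv3_w", "dense1_w", "dense5_b"):
            flat = net.params[key].ravel()
            for i in rng.choice(flat.size, size=3, replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss_now()
                flat[i] = old - eps
                lm = loss_now()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert grads[key].ravel()[i] == pytest.approx(num, rel=1e-3, abs=1e-7)


def _toy_training_data(n, seed=0, two_classes=False):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 4, 200)) * 0.3
    Z = rng.standard_normal((n, 3)) * 0.1
    if two_classes:
        t1 = np.array([1.6, 2.0, 18.2, 0.4])
        t2 = np.array([0.5, 0.0, 5.0, 0.1])
        Y = np.where((np.arange(n) % 2 == 0)[:, None], t1, t2)
        X[::2] += 1.0  # separable signal
    else:
        Y = np.column_stack(
            [rng.uniform(0.3, 2, n), rng.uniform(0, 2, n), rng.uniform(2, 30, n),
             rng.uniform(0, 0.6, n)]
        )
        # plant a learnable signal: first-channel mean tracks y_c
        X[:, 0, :] += (Y[:, 2:3] - 16) / 30
    return X, Z, Y


class TestTraining:
    def test_loss_decreases(self):
        X, Z, Y = _toy_training_data(400, seed=1)
        net = build_network(NetworkSpec(), seed=1)
        hist = train(net, X, Z, Y, TrainConfig(epochs=8, seed=0))
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert len(hist.train_loss) == 8
        assert hist.test_loss is not None and np.isfinite(hist.test_loss)

    def test_two_class_sample_overfits_to_low_loss(self):
        # degenerate sample with only two truth parameter sets: trained to
        # convergence, per-tree losses collapse into two modes near zero
        X, Z, Y = _toy_training_data(256, seed=2, two_classes=True)
        net = build_network(NetworkSpec(), seed=3)
        train(net, X, Z, Y, TrainConfig(epochs=120, seed=0))
        g = affinity_grid()
        out = net.forward(X, Z)
        losses, _ = _sigmoid_head_loss_grad(out, Y, g)
        assert np.median(losses[::2]) < 0.25
        assert np.median(losses[1::2]) < 0.25
        # and the predictions separate into two clusters tracking the truths
        gap = np.abs(out[::2].mean(axis=0) - out[1::2].mean(axis=0))
        assert gap[2] > 5.0  # y_c differs by >5 births/day between clusters

    def test_per_bin_training_runs(self):
        X, Z, Y = _toy_training_data(128, seed=4)
        net = build_network(NetworkSpec(head="per_bin"), seed=0)
        hist = train(net, X, Z, Y, TrainConfig(epochs=3, seed=0))
        assert hist.train_loss[-1] < hist.train_loss[0] * 1.5
        out = net.forward(X[:8], Z[:8])
        assert out.shape == (8, 11)
        assert np.all(out >= 0)


class TestTrainedModel:
    def _model_with_scaler(self):
        net = build_network(NetworkSpec(), seed=5)
        scaler = InputScaler(
            branch_mean=0.1, branch_std=0.2, affinity_mean=0.0, affinity_std=1.0,
            nonsigmoid_mean=np.array([150.0, 16.0, 0.2]),
            nonsigmoid_std=np.array([50.0, 8.0, 0.1]),
        )
        return TrainedModel(net=net, scaler=scaler, history=TrainHistory())

    def _toy_encoded(self, n=3):
        rng = np.random.default_rng(0)
        encs = []
        for _ in range(n):
            m = np.zeros((4, 200))
            m[0, :30] = rng.uniform(0.05, 1, 30)
            m[1, :29] = rng.uniform(0.05, 1, 29)
            m[2, :30] = rng.normal(size=30)
            m[3, :29] = rng.normal(size=29)
            encs.append(EncodedTree(matrix=m, n_leaves=30, n_internal=29))
        return encs

    def test_prediction_deterministic(self):
        model = self._model_with_scaler()
        encs = self._toy_encoded()
        ns = np.array([200.0, 32.0, 0.2])
        p1 = model.predict_params(encs, ns)
        p2 = model.predict_params(encs, ns)
        np.testing.assert_array_equal(p1, p2)

    def test_nonsigmoid_values_change_prediction(self):
        model = self._model_with_scaler()
        encs = self._toy_encoded()
        p1 = model.predict_params(encs, np.array([100.0, 8.0, 0.05]))
        p2 = model.predict_params(encs, np.array([2000.0, 128.0, 0.4]))
        assert not np.allclose(p1, p2)

    def test_missing_scaler_rejected(self):
        model = self._model_with_scaler()
        model.scaler = None
        with pytest.raises(ValueError, match="scaler"):
            model.predict_params(self._toy_encoded(), np.array([100.0, 8.0, 0.05]))

    def test_save_load_roundtrip(self, tmp_path):
        model = self._model_with_scaler()
        encs = self._toy_encoded()
        ns = np.array([150.0, 16.0, 0.2])
        before = model.predict_params(encs, ns)
        model.save(tmp_path / "model")
        back = TrainedModel.load(tmp_path / "model")
        after = back.predict_params(encs, ns)
        np.testing.assert_allclose(after, before, atol=1e-12)
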