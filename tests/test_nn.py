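"""Numpy CNN engine: gradient correctness, layer contracts, forward shapes."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from conftest import tiny_architecture
from thermofract.architecture import build_architecture
from thermofract.nn import (
    Adam,
    BatchNorm2D,
    Conv2D,
    Dense,
    MaxPool2,
    Network,
    ReLU,
    softmax,
    softmax_cross_entropy,
)


def finite_difference_check(net, x, y, eps=1e-6, atol=1e-5, rtol=1e-3):
    """Compare analytic gradients against central differences."""
    def loss_fn():
        return softmax_cross_entropy(net.forward(x, training=True), y)[0]

    logits = net.forward(x, training=True)
    _, dlogits = softmax_cross_entropy(logits, y)
    net.backward(dlogits)
    analytic = {p["name"]: p["grad"]().copy() for p in net.params()}

    for p in net.params():
        flat = p["value"].reshape(-1)
        for k in range(flat.size):
            orig = flat[k]
            flat[k] = orig + eps
            lp = loss_fn()
            flat[k] = orig - eps
            lm = loss_fn()
            flat[k] = orig
            num = (lp - lm) / (2 * eps)
            ana = analytic[p["name"]].reshape(-1)[k]
            assert abs(num - ana) <= atol + rtol * max(abs(num), abs(ana)), (
                f"{p['name']}[{k}]: numeric {num} vs analytic {ana}")


class TestGradients:
    def test_conv_relu_pool_fc_gradients(self):
        net = Network(tiny_architecture(with_batchnorm=False), seed=1, dtype=np.float64)
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(4, 8, 8)), rng.integers(0, 2, 4)
        finite_difference_check(net, x, y)

    def test_full_block_with_batchnorm_gradients(self):
        net = Network(tiny_architecture(with_batchnorm=True), seed=2, dtype=np.float64)
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(6, 8, 8)), rng.integers(0, 2, 6)
        finite_difference_check(net, x, y)


class TestLayerContracts:
    def test_conv_matches_scipy_correlate_oracle(self):
        rng = np.random.default_rng(3)
        conv = Conv2D(2, 3, rng, dtype=np.float64)
        x = rng.normal(size=(1, 2, 9, 7))
        out = conv.forward(x)
        for f in range(3):
            expected = sum(
                correlate2d(x[0, c], conv.weight[f, c], mode="same") for c in range(2)
            ) + conv.bias[f]
            assert np.allclose(out[0, f], expected, atol=1e-12)

    def test_batchnorm_standardizes_training_batches(self):
        # default scale 1, offset 0: per-channel mean ~0, sd ~1
        bn = BatchNorm2D(3, dtype=np.float64)
        rng = np.random.default_rng(4)
        x = rng.normal(5.0, 2.5, size=(16, 3, 6, 6))
        out = bn.forward(x, training=True)
        for c in range(3):
            assert abs(out[:, c].mean()) < 1e-5
            assert out[:, c].std() == pytest.approx(1.0, abs=1e-3)

    def test_relu_outputs_never_negative_through_full_network(self):
        net = Network(build_architecture(), seed=5)
        rng = np.random.default_rng(5)
        h = net._prepare(rng.normal(size=(2, 100, 100)))
        for layer in net.layers:
            if isinstance(layer, Dense) and h.ndim == 4:
                h = h.reshape(h.shape[0], -1)
            h = layer.forward(h, training=True)
            if isinstance(layer, ReLU):
                assert h.min() >= 0.0

    def test_maxpool_floor_drops_odd_border(self):
        x = np.arange(25.0).reshape(1, 1, 5, 5)
        out = MaxPool2().forward(x)
        assert out.shape == (1, 1, 2, 2)
        assert np.array_equal(out[0, 0], [[6, 8], [16, 18]])

    def test_maxpool_backward_routes_to_argmax_only(self):
        pool = MaxPool2()
        x = np.arange(16.0).reshape(1, 1, 4, 4)
        pool.forward(x)
        dx = pool.backward(np.ones((1, 1, 2, 2)))
        assert dx.sum() == 4.0
        assert np.array_equal(np.argwhere(dx[0, 0] > 0),
                              [[1, 1], [1, 3], [3, 1], [3, 3]])


class TestNetworkForward:
    def test_probability_rows_sum_to_one(self):
        net = Network(build_architecture(), seed=6)
        x = np.random.default_rng(6).normal(size=(3, 100, 100))
        proba = net.predict_proba(x)
        assert proba.shape == (3, 2)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert proba.min() >= 0.0

    def test_zero_weight_network_predicts_half_half(self):
        net = Network(build_architecture(), seed=7)
        net.zero_weights()
        proba = net.predict_proba(np.random.default_rng(7).normal(size=(2, 100, 100)))
        assert np.allclose(proba, 0.5)

    def test_tie_at_threshold_resolves_to_non_fracture(self):
        net = Network(build_architecture(), seed=8)
        net.zero_weights()
        assert np.all(net.predict(np.zeros((2, 100, 100))) == 0)

    def test_wrong_input_shape_rejected(self):
        net = Network(tiny_architecture(), seed=9)
        with pytest.raises(ValueError):
            net.forward(np.zeros((2, 10, 10)))

    def test_dropout_active_only_in_training(self):
        arch = build_architecture("dropout_no_augmentation")
        net = Network(arch, seed=10)
        x = np.random.default_rng(10).normal(size=(2, 100, 100))
        assert np.array_equal(net.forward(x), net.forward(x))  # eval is deterministic


def test_adam_reduces_a_quadratic_loss():
    rng = np.random.default_rng(11)
    value = rng.normal(size=(5,))
    grad_holder = {"g": np.zeros(5)}
    params = [{"name": "w", "value": value, "grad": lambda: grad_holder["g"]}]
    opt = Adam(params, learning_rate=0.1)
    for _ in range(200):
        grad_holder["g"] = 2 * value
        opt.step()
    assert np.abs(value).max() < 1e-3


def test_softmax_is_shift_invariant_and_normalized():
    logits = np.array([[1000.0, 1002.0], [-5.0, 3.0]])
    p = softmax(logits)
    assert np.allclose(p.sum(axis=1), 1.0)
    assert np.allclose(p, softmax(logits + 123.0))
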