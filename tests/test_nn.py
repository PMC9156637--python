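"""Gradient correctness of the conv-net engine via finite differences."""

import numpy as np
import pytest

from minipae import nn


@pytest.fixture
def f64(monkeypatch):
    """Run layers in float64 so finite differences are tight."""
    monkeypatch.setattr(nn, "DTYPE", np.float64)
    return np.float64


def num_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def _cast64(layer):
    for p in layer.params():
        p.value = p.value.astype(np.float64)
        p.grad = np.zeros_like(p.value)
    return layer


def test_conv2d_gradients(f64, rng):
    conv = _cast64(nn.Conv2d(2, 3, 4, 2, 1, rng))
    x = rng.standard_normal((2, 2, 8, 8))
    up = rng.standard_normal((2, 3, 4, 4))

    def loss():
        y, _ = conv.forward(x)
        return float((y * up).sum())

    y, cache = conv.forward(x)
    dx = conv.backward(up, cache)
    assert np.abs(dx - num_grad(loss, x)).max() < 1e-7
    assert np.abs(conv.W.grad - num_grad(loss, conv.W.value)).max() < 1e-7
    assert np.abs(conv.b.grad - num_grad(loss, conv.b.value)).max() < 1e-7


def test_conv_transpose_gradients_and_shape(f64, rng):
    ct = _cast64(nn.ConvTranspose2d(3, 2, 4, 2, 1, rng))
    x = rng.standard_normal((2, 3, 4, 4))
    up = rng.standard_normal((2, 2, 8, 8))

    def loss():
        y, _ = ct.forward(x)
        return float((y * up).sum())

    y, cache = ct.forward(x)
    assert y.shape == (2, 2, 8, 8)  # stride-2 doubling
    dx = ct.backward(up, cache)
    assert np.abs(dx - num_grad(loss, x)).max() < 1e-7
    assert np.abs(ct.W.grad - num_grad(loss, ct.W.value)).max() < 1e-7


def test_conv_transpose_is_adjoint_of_conv(f64, rng):
    """<conv(x), y> == <x, convT(y)> when they share a weight tensor."""
    conv = _cast64(nn.Conv2d(2, 3, 4, 2, 1, rng))
    ct = _cast64(nn.ConvTranspose2d(3, 2, 4, 2, 1, rng))
    ct.W.value = np.transpose(conv.W.value, (0, 1, 2, 3)).copy()  # (F,C,k,k)
    # conv weight (F=3, C=2); convT expects (cin=3, cout=2): same layout
    ct.W.value = conv.W.value.copy()
    conv.b.value[:] = 0
    ct.b.value[:] = 0
    x = rng.standard_normal((1, 2, 8, 8))
    y = rng.standard_normal((1, 3, 4, 4))
    cx, _ = conv.forward(x)
    cty, _ = ct.forward(y)
    assert float((cx * y).sum()) == pytest.approx(float((x * cty).sum()), rel=1e-9)


def test_batchnorm_gradients_train_mode(f64, rng):
    import copy

    bn = _cast64(nn.BatchNorm2d(3))
    bn.running_mean = bn.running_mean.astype(np.float64)
    bn.running_var = bn.running_var.astype(np.float64)
    x = rng.standard_normal((4, 3, 5, 5))
    up = rng.standard_normal((4, 3, 5, 5))

    def loss():
        b = copy.deepcopy(bn)  # keep running stats frozen
        y, _ = b.forward(x, train=True)
        return float((y * up).sum())

    y, cache = bn.forward(x, train=True)
    dx = bn.backward(up, cache)
    assert np.abs(dx - num_grad(loss, x)).max() < 1e-6
    assert np.abs(bn.gamma.grad - num_grad(loss, bn.gamma.value)).max() < 1e-6


def test_batchnorm_eval_uses_running_stats(rng):
    bn = nn.BatchNorm2d(2)
    x = rng.standard_normal((8, 2, 4, 4)).astype(np.float32)
    for _ in range(200):
        bn.forward(x, train=True)
    y, _ = bn.forward(x, train=False)
    yt, _ = bn.forward(x, train=True)
    np.testing.assert_allclose(y, yt, atol=1e-2)


def test_dropout_scaling_and_eval_identity(rng):
    d = nn.Dropout(0.5)
    x = np.ones((1, 1, 50, 50))
    y, mask = d.forward(x, train=True, rng=rng)
    assert set(np.unique(y)).issubset({0.0, 2.0})  # inverted scaling
    ye, _ = d.forward(x, train=False)
    assert np.array_equal(ye, x)


def test_bce_with_logits_matches_naive(rng):
    logits = rng.standard_normal(10)
    p = 1 / (1 + np.exp(-logits))
    naive = -np.mean(np.log(p))
    assert nn.bce_with_logits(logits, 1.0) == pytest.approx(naive, rel=1e-9)
    g = nn.bce_with_logits_grad(logits, 1.0)
    eps = 1e-6
    num = ((nn.bce_with_logits(logits + eps * np.eye(10)[0], 1.0))
           - nn.bce_with_logits(logits - eps * np.eye(10)[0], 1.0)) / (2 * eps)
    assert g[0] == pytest.approx(num, abs=1e-6)


def test_adam_minimises_quadratic():
    p = nn.Param(np.array([5.0, -3.0]))
    opt = nn.Adam([p], lr=0.1)
    for _ in range(500):
        opt.zero_grad()
        p.grad += 2 * p.value
        opt.step()
    assert np.abs(p.value).max() < 1e-2
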