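"""A compact CPU convolutional-network engine on numpy.

Implements exactly the pieces the adversarial auto-encoder needs — strided
4x4 convolutions and transposed convolutions (im2col / col2im with exact
adjoint pairing), batch normalisation with running statistics, leaky ReLU,
tanh, dropout and Adam — with explicit forward caches and hand-written
backward passes. Layers are functional: ``forward`` returns ``(y, cache)``
and ``backward(dy, cache)`` returns ``dx`` while accumulating parameter
gradients, so the same layer can be run on several batches per step (the
discriminator sees both real and generated images).

All gradients are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: computation dtype; float32 doubles CPU throughput and is ample for
#: adversarial training
DTYPE = np.float32


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


# ---------------------------------------------------------------- im2col

def im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, C*k*k, OH*OW) patch matrix."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, oh, ow = win.shape[:4]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def col2im(cols: np.ndarray, n: int, c: int, h: int, w: int, k: int, stride: int, pad: int):
    """Adjoint of :func:`im2col`: scatter-add patches back onto the image."""
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols6 = cols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols6[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w]


# ----------------------------------------------------------------- layers

class Conv2d:
    """Strided convolution; the 4x4/stride-2 setting halves spatial size."""

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None):
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.W = Param(rng.normal(0.0, 0.02, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True, rng=None):
        cols, oh, ow = im2col(x, self.k, self.stride, self.pad)
        wm = self.W.value.reshape(self.cout, -1)
        y = np.matmul(wm[None], cols) + self.b.value[None, :, None]
        return y.reshape(x.shape[0], self.cout, oh, ow), (x.shape, cols)

    def backward(self, dy, cache):
        (n, cin, h, w), cols = cache
        dym = dy.reshape(n, self.cout, -1)
        wm = self.W.value.reshape(self.cout, -1)
        self.W.grad += np.tensordot(dym, cols, axes=([0, 2], [0, 2])).reshape(self.W.value.shape)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dcols = np.matmul(wm.T[None], dym)
        return col2im(dcols, n, cin, h, w, self.k, self.stride, self.pad)


class ConvTranspose2d:
    """Transposed convolution: the exact adjoint of :class:`Conv2d`.

    With k=4, stride=2, pad=1 it doubles spatial size, mirroring the
    encoder's halving.
    """

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None):
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.W = Param(rng.normal(0.0, 0.02, size=(cin, cout, k, k)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def _out_hw(self, h, w):
        s, p, k = self.stride, self.pad, self.k
        return (h - 1) * s - 2 * p + k, (w - 1) * s - 2 * p + k

    def forward(self, x, train=True, rng=None):
        n, cin, h, w = x.shape
        oh, ow = self._out_hw(h, w)
        xf = x.reshape(n, cin, h * w)
        wm = self.W.value.reshape(cin, -1)  # (cin, cout*k*k)
        cols = np.matmul(wm.T[None], xf)  # (n, cout*k*k, h*w)
        y = col2im(cols, n, self.cout, oh, ow, self.k, self.stride, self.pad)
        return y + self.b.value[None, :, None, None], (x, (oh, ow))

    def backward(self, dy, cache):
        x, (oh, ow) = cache
        n, cin, h, w = x.shape
        dcols, oh2, ow2 = im2col(dy, self.k, self.stride, self.pad)
        assert (oh2, ow2) == (h, w)
        xf = x.reshape(n, cin, h * w)
        self.W.grad += np.tensordot(xf, dcols, axes=([0, 2], [0, 2])).reshape(self.W.value.shape)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        wm = self.W.value.reshape(cin, -1)
        dx = np.matmul(wm[None], dcols)
        return dx.reshape(n, cin, h, w)


class BatchNorm2d:
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True, rng=None):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        return y, (xhat, invstd, train, x.shape)

    def backward(self, dy, cache):
        xhat, invstd, train, shape = cache
        g = self.gamma.value[None, :, None, None]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        if not train:
            return dy * g * invstd[None, :, None, None]
        n = shape[0] * shape[2] * shape[3]
        dxhat = dy * g
        # standard batch-norm backward, vectorised per channel
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) - xhat * (
            (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        return term * invstd[None, :, None, None]


class LeakyReLU:
    def __init__(self, slope=0.2):
        self.slope = slope

    def params(self):
        return []

    def forward(self, x, train=True, rng=None):
        mask = x >= 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, dy, mask):
        return np.where(mask, dy, self.slope * dy)


class Tanh:
    def params(self):
        return []

    def forward(self, x, train=True, rng=None):
        y = np.tanh(x)
        return y, y

    def backward(self, dy, y):
        return dy * (1.0 - y * y)


class Dropout:
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p=0.25):
        self.p = p

    def params(self):
        return []

    def forward(self, x, train=True, rng=None):
        if not train or self.p <= 0:
            return x, None
        rng = rng or np.random.default_rng()
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask, mask

    def backward(self, dy, mask):
        return dy if mask is None else dy * mask


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def bce_with_logits(logits, target):
    """Numerically stable binary cross-entropy from logits (mean)."""
    z = np.asarray(logits, dtype=np.float64)
    loss = np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))
    return float(loss.mean())


def bce_with_logits_grad(logits, target):
    """d(mean BCE)/d logits."""
    return (sigmoid(logits) - target) / logits.size


class Adam:
    def __init__(self, params, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad**2 - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
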