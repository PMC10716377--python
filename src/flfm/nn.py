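"""Minimal convolutional network layers in pure NumPy.

Every layer implements an explicit ``forward``/``backward`` pair
(reverse-mode gradients, no tape), which keeps training fully
deterministic on CPU under a fixed seed and leaves no dependencies
beyond NumPy.  Shapes follow the (batch, channel, height, width)
convention; convolutions are 'same'-padded with odd kernels and support
stride 1-2 and dilation, which is all the F-VCD architecture needs.

Gradient correctness of each layer is pinned by finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


DTYPE = np.float32      # single precision: 2x faster on CPU, ample for SGD


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]):
        for p, v in zip(self.params(), state, strict=True):
            p.value[...] = v


class Conv2d(Module):
    """'Same'-padded 2D convolution (cross-correlation), He-initialized."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 dilation: int = 1, rng: np.random.Generator | None = None):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self.k, self.stride, self.dilation = k, stride, dilation

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        k, s, d = self.k, self.stride, self.dilation
        keff = (k - 1) * d + 1
        pad = keff // 2
        xp = np.pad(np.asarray(x, dtype=DTYPE),
                    ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = sliding_window_view(xp, (keff, keff), axis=(2, 3))
        win = win[:, :, ::s, ::s, ::d, ::d]
        y = np.einsum("bchwij,ocij->bohw", win, self.W.value, optimize=True)
        y += self.b.value[None, :, None, None]
        if train:
            self._cache = (x.shape, xp.shape, win)
        return y

    def backward(self, g):
        x_shape, xp_shape, win = self._cache
        k, s, d = self.k, self.stride, self.dilation
        pad = ((k - 1) * d + 1) // 2
        g = np.asarray(g, dtype=DTYPE)
        self.W.grad += np.einsum("bohw,bchwij->ocij", g, win, optimize=True)
        self.b.grad += g.sum(axis=(0, 2, 3))
        gxp = np.zeros(xp_shape, dtype=DTYPE)
        hout, wout = g.shape[2:]
        for i in range(k):
            for j in range(k):
                contrib = np.einsum("bohw,oc->bchw", g, self.W.value[:, :, i, j],
                                    optimize=True)
                gxp[:, :, i * d:i * d + s * hout:s,
                    j * d:j * d + s * wout:s] += contrib
        h, w = x_shape[2:]
        return gxp[:, :, pad:pad + h, pad:pad + w]


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.1):
        self.slope = slope

    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.where(x > 0, x, self.slope * x)

    def backward(self, g):
        return np.where(self._mask, g, self.slope * g)


class Sigmoid(Module):
    def forward(self, x, train=True):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        if train:
            self._y = y
        return y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over (H, W), affine."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, g):
        xhat, inv = self._cache
        self.gamma.grad += np.sum(g * xhat, axis=(0, 2, 3))
        self.beta.grad += np.sum(g, axis=(0, 2, 3))
        gh = g * self.gamma.value[None, :, None, None]
        m1 = gh.mean(axis=(2, 3), keepdims=True)
        m2 = (gh * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (gh - m1 - xhat * m2)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class Residual(Module):
    """y = x + inner(x); inner must preserve shape."""

    def __init__(self, inner: Module):
        self.inner = inner

    def params(self):
        return self.inner.params()

    def forward(self, x, train=True):
        return x + self.inner.forward(x, train=train)

    def backward(self, g):
        return g + self.inner.backward(g)


class ChannelAttention(Module):
    """Squeeze-excite gate: y = x * sigmoid(MLP(global mean pool(x))).

    With the input channels being light-field views this *is* the
    view-attention branch: one sigmoid weight per view.
    """

    def __init__(self, c: int, reduction: int = 2,
                 rng: np.random.Generator | None = None):
        hidden = max(c // reduction, 2)
        self.fc1 = Conv2d(c, hidden, k=1, rng=rng)
        self.act = LeakyReLU(0.1)
        self.fc2 = Conv2d(hidden, c, k=1, rng=rng)
        self.sig = Sigmoid()

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def forward(self, x, train=True):
        p = x.mean(axis=(2, 3), keepdims=True)
        s = self.sig.forward(
            self.fc2.forward(self.act.forward(
                self.fc1.forward(p, train), train), train), train)
        if train:
            self._cache = (x, s)
        return x * s

    def backward(self, g):
        x, s = self._cache
        gx_direct = g * s
        gs = np.sum(g * x, axis=(2, 3), keepdims=True)
        gp = self.fc1.backward(self.act.backward(
            self.fc2.backward(self.sig.backward(gs))))
        hw = x.shape[2] * x.shape[3]
        return gx_direct + gp / hw


class UpsampleNearest2(Module):
    def forward(self, x, train=True):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g):
        b, c, h, w = g.shape
        return g.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class PixelShuffle(Module):
    """(B, C*r^2, H, W) -> (B, C, H*r, W*r) sub-pixel upsampling."""

    def __init__(self, r: int):
        self.r = r

    def forward(self, x, train=True):
        b, crr, h, w = x.shape
        r = self.r
        c = crr // (r * r)
        y = x.reshape(b, c, r, r, h, w).transpose(0, 1, 4, 2, 5, 3)
        return y.reshape(b, c, h * r, w * r)

    def backward(self, g):
        b, c, hr, wr = g.shape
        r = self.r
        h, w = hr // r, wr // r
        y = g.reshape(b, c, h, r, w, r).transpose(0, 1, 3, 5, 2, 4)
        return y.reshape(b, c * r * r, h, w)


class Adam:
    """Adam with an exponentially decaying learning rate."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 lr_decay: float = 1.0):
        self.params = params
        self.lr0 = lr
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.lr_decay = lr_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def decay_epoch(self):
        self.lr *= self.lr_decay

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
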