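"""Minimal NumPy neural-network layers with explicit backpropagation.

Implements exactly the pieces a 2D U-net needs — 3x3 "same" convolution,
batch normalization, ReLU, 2x2 max pooling, 2x2-stride-2 transposed
convolution, Tanhshrink — plus the Adam optimizer.  Layers operate on
channels-last ``(B, H, W, C)`` float32 tensors (convolution becomes a
handful of BLAS matmuls over the channel axis, by far the fastest layout
for a pure NumPy CPU implementation); the network front-end converts
from the package-wide channels-first convention at its boundary.

Each layer caches what its ``backward`` needs during ``forward``;
``backward`` consumes the gradient of the loss w.r.t. the layer output
and returns it w.r.t. the input while accumulating parameter gradients
in ``layer.grads``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "BatchNorm2d", "ReLU", "Tanhshrink", "MaxPool2d",
    "ConvTranspose2d", "Adam", "tanhshrink",
]


def tanhshrink(x: np.ndarray) -> np.ndarray:
    """Output activation x - tanh(x): ~0 near the origin, linear in the tails."""
    return x - np.tanh(x)


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Conv2d(Layer):
    """k x k convolution, "same" zero padding, stride 1, channels-last.

    Implemented as a sum of k*k channel-mixing matmuls on shifted views
    of the zero-padded input.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, rng=None):
        super().__init__()
        rng = np.random.default_rng() if rng is None else rng
        std = np.sqrt(2.0 / (cin * k * k))  # He init for ReLU stacks
        self.w = (rng.standard_normal((k, k, cin, cout)) * std).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k = k
        self.pad = (k - 1) // 2
        self.cin, self.cout = cin, cout
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        b, h, w, _ = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._xp, self._hw = xp, (h, w)
        out = np.empty((b, h, w, self.cout), dtype=np.float32)
        out[...] = self.b
        for i in range(self.k):
            for j in range(self.k):
                out += xp[:, i:i + h, j:j + w, :] @ self.w[i, j]
        return out

    def backward(self, gout):
        h, w = self._hw
        p = self.pad
        xp = self._xp
        gxp = np.zeros_like(xp)
        for i in range(self.k):
            for j in range(self.k):
                self.grads[0][i, j] += np.einsum(
                    "bhwc,bhwo->co", xp[:, i:i + h, j:j + w, :], gout, optimize=True
                )
                gxp[:, i:i + h, j:j + w, :] += gout @ self.w[i, j].T
        self.grads[1] += gout.sum(axis=(0, 1, 2))
        return gxp[:, p:p + h, p:p + w, :] if p else gxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv
        self._xhat, self._inv, self._train = xhat, inv, train
        return self.gamma * xhat + self.beta

    def backward(self, gout):
        xhat, inv = self._xhat, self._inv
        self.grads[0] += (gout * xhat).sum(axis=(0, 1, 2))
        self.grads[1] += gout.sum(axis=(0, 1, 2))
        g = gout * self.gamma
        if not self._train:
            return g * inv
        n = gout.shape[0] * gout.shape[1] * gout.shape[2]
        t1 = g.sum(axis=(0, 1, 2))
        t2 = (g * xhat).sum(axis=(0, 1, 2))
        return (inv / n) * (n * g - t1 - xhat * t2)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, gout):
        return gout * self._mask


class Tanhshrink(Layer):
    def forward(self, x, train=True):
        self._t = np.tanh(x)
        return x - self._t

    def backward(self, gout):
        return gout * self._t**2


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2, channels-last."""

    def forward(self, x, train=True):
        b, h, w, c = x.shape
        r = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        r = np.ascontiguousarray(r).reshape(b, h // 2, w // 2, c, 4)
        idx = r.argmax(axis=-1)
        self._idx, self._shape = idx, (b, h, w, c)
        return np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(self, gout):
        b, h, w, c = self._shape
        g = np.zeros((b, h // 2, w // 2, c, 4), dtype=gout.dtype)
        np.put_along_axis(g, self._idx[..., None], gout[..., None], axis=-1)
        g = g.reshape(b, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(g).reshape(b, h, w, c)


class ConvTranspose2d(Layer):
    """2x2 transposed convolution, stride 2 (non-overlapping upsampling)."""

    def __init__(self, cin: int, cout: int, rng=None):
        super().__init__()
        rng = np.random.default_rng() if rng is None else rng
        std = np.sqrt(2.0 / cin)
        self.w = (rng.standard_normal((cin, 4 * cout)) * std).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.cin, self.cout = cin, cout
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        b, h, w, _ = x.shape
        self._x = x
        out = (x @ self.w).reshape(b, h, w, 2, 2, self.cout)
        out = out.transpose(0, 1, 3, 2, 4, 5).reshape(b, 2 * h, 2 * w, self.cout)
        return out + self.b

    def backward(self, gout):
        b, h2, w2, _ = gout.shape
        h, w = h2 // 2, w2 // 2
        g = gout.reshape(b, h, 2, w, 2, self.cout).transpose(0, 1, 3, 2, 4, 5)
        g = np.ascontiguousarray(g).reshape(b, h, w, 4 * self.cout)
        self.grads[0] += np.einsum("bhwc,bhwk->ck", self._x, g, optimize=True)
        self.grads[1] += gout.sum(axis=(0, 1, 2))
        return g @ self.w.T


class Adam:
    """Adam with a mutable learning rate (for plateau scheduling)."""

    def __init__(self, params: list, lr: float = 2e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
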