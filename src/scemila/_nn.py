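"""Minimal numpy neural-network layers (NCHW convention).

Forward passes are vectorized through im2col; backward passes are implemented
for the layers the trainable tiny-CNN path uses. The ResNet34 backbone uses
forward mode only (feature extraction / architecture arithmetic).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


class Layer:
    """Base class: ``params`` / ``grads`` are parallel lists of arrays."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kh, kw = _pair(kernel)
        fan_in = c_in * kh * kw
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, kh, kw)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32) if bias else None
        self.stride, self.pad = stride, pad
        self.params = [self.W] + ([self.b] if bias else [])
        self.grads = [np.zeros_like(p) for p in self.params]
        self._cache = None

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        n, c, h, w = x.shape
        kh, kw = self.W.shape[2:]
        s, p = self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        windows = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
        oh, ow = windows.shape[2], windows.shape[3]
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
        return np.ascontiguousarray(cols), (n, c, h, w, oh, ow)

    def forward(self, x, train=False):
        cols, shape = self._im2col(x)
        n, c, h, w, oh, ow = shape
        c_out = self.W.shape[0]
        out = cols @ self.W.reshape(c_out, -1).T
        if self.b is not None:
            out += self.b
        out = out.reshape(n, oh, ow, c_out).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, shape)
        return out

    def backward(self, dout):
        cols, (n, c, h, w, oh, ow) = self._cache
        c_out, _, kh, kw = self.W.shape
        s, p = self.stride, self.pad
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.grads[0] += (dflat.T @ cols).reshape(self.W.shape)
        if self.b is not None:
            self.grads[1] += dflat.sum(axis=0)
        dcols = (dflat @ self.W.reshape(c_out, -1)).reshape(n, oh, ow, c, kh, kw)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for ki in range(kh):
            for kj in range(kw):
                dxp[:, :, ki:ki + oh * s:s, kj:kj + ow * s:s] += \
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    """Forward-only max pooling (used by the inference backbone)."""

    def __init__(self, kernel: int, stride: int, pad: int = 0):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x, train=False):
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                       constant_values=-np.inf)
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        return win.max(axis=(4, 5))


class GlobalAvgPool(Layer):
    """2D average pooling over the full spatial extent -> (N, C)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).copy()


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0] += self._x.T @ dout
        self.grads[1] += dout.sum(axis=0)
        return dout @ self.W.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    @property
    def all_params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def all_grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grads(self) -> None:
        for g in self.all_grads:
            g[...] = 0


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max subtraction)."""
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy of predicted ``probs`` vs integer labels."""
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + eps)))


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    def __init__(self, params, grads, lr: float = 1e-2, momentum: float = 0.9):
        self.params, self.grads, self.lr, self.mu = params, grads, lr, momentum
        self.vel = [np.zeros_like(p) for p in params]

    def step(self) -> None:
        for p, g, v in zip(self.params, self.grads, self.vel):
            v[...] = self.mu * v - self.lr * g
            p += v
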