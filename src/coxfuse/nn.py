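"""Minimal feed-forward neural stack on numpy.

Layers cache what their backward pass needs, gradients are accumulated per
parameter, and :class:`Adam` updates parameter groups with independent learning
rates (joint fusion trains its two branches and head at different rates).
Every stochastic element (init, dropout masks) draws from an explicit
``numpy.random.Generator`` so runs are bit-reproducible under a fixed seed.

Shapes follow the NCHW convention for images and (N, F) for dense inputs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "ReLU",
    "Dropout",
    "Conv2d",
    "MaxPool2d",
    "Flatten",
    "Sequential",
    "Adam",
]


class Layer:
    """Base class: forward caches, backward returns grad w.r.t. input."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def zero_grad(self) -> None:
        for g in self.grads():
            g[...] = 0.0


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init: str = "he") -> None:
        scale = np.sqrt(2.0 / n_in) if init == "he" else np.sqrt(1.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float64)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | float = 1.0

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    """(N, C, H, W) -> (N, out_h, out_w, C*k*k) using stride tricks."""
    n, c, h, w = x.shape
    out_h = (h - k) // stride + 1
    out_w = (w - k) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, out_h, out_w, k, k),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False,
    )
    col = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, out_h, out_w, c * k * k)
    return col, out_h, out_w


class Conv2d(Layer):
    """Valid (no padding) 2-D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1) -> None:
        self.k, self.stride, self.c_in, self.c_out = k, stride, c_in, c_out
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = (rng.standard_normal((c_in * k * k, c_out)) * scale).astype(np.float64)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x_shape = x.shape
        col, oh, ow = _im2col(x, self.k, self.stride)
        self._col = col.reshape(-1, col.shape[-1])
        y = self._col @ self.W + self.b
        return y.reshape(x.shape[0], oh, ow, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, c_out, oh, ow = dy.shape
        dy_flat = dy.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.dW += self._col.T @ dy_flat
        self.db += dy_flat.sum(axis=0)
        dcol = dy_flat @ self.W.T  # (N*oh*ow, C*k*k)
        dx = np.zeros(self._x_shape)
        dcol = dcol.reshape(n, oh, ow, self.c_in, self.k, self.k)
        # scatter-add the column gradients back onto the input raster
        for i in range(self.k):
            for j in range(self.k):
                dx[:, :, i:i + oh * self.stride:self.stride,
                   j:j + ow * self.stride:self.stride] += dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class MaxPool2d(Layer):
    def __init__(self, k: int) -> None:
        self.k = k

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k = self.k
        oh, ow = h // k, w // k
        self._x_shape = x.shape
        xr = x[:, :, :oh * k, :ow * k].reshape(n, c, oh, k, ow, k)
        xw = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, k * k)
        self._argmax = xw.argmax(axis=-1)
        return xw.max(axis=-1)

    def backward(self, dy):
        n, c, oh, ow = dy.shape
        k = self.k
        dxw = np.zeros((n, c, oh, ow, k * k))
        np.put_along_axis(dxw, self._argmax[..., None], dy[..., None], axis=-1)
        dx = np.zeros(self._x_shape)
        dx[:, :, :oh * k, :ow * k] = (
            dxw.reshape(n, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, oh * k, ow * k)
        )
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state, strict=True):
            p[...] = s


class Adam:
    """Adam over parameter groups, each group with its own learning rate.

    ``groups`` is a list of ``(params, grads, lr)`` triples; a zero learning
    rate freezes its group exactly (no moment updates either).
    """

    def __init__(self, groups: list[tuple[list[np.ndarray], list[np.ndarray], float]],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.groups = groups
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in params] for params, _, _ in groups]
        self.v = [[np.zeros_like(p) for p in params] for params, _, _ in groups]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for gi, (params, grads, lr) in enumerate(self.groups):
            if lr == 0.0:
                continue
            for pi, (p, g) in enumerate(zip(params, grads, strict=True)):
                m = self.m[gi][pi]
                v = self.v[gi][pi]
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for _, grads, _ in self.groups:
            for g in grads:
                g[...] = 0.0
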