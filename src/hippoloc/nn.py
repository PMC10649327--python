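"""Minimal numpy neural-network core: N-D convolution, pooling, dense layers,
activations, Adam, and the Smooth-L1 / classification losses.

Implements exactly the layer vocabulary the localization and classification
networks need (Conv + LeakyReLU, MaxPool, Flatten, Dense, ReLU, Sigmoid) with
explicit backward passes.  Convolutions use ``same`` zero-padding so the stack
stays well-defined on the small crops used by the fast profiles as well as on
full 256x256 slices.  All initialization is driven by a caller-supplied
``numpy.random.Generator`` so builds are reproducible bit-for-bit.

Gradient correctness is enforced by finite-difference tests; do not "optimize"
a backward pass without re-running them.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv",
    "MaxPool",
    "Dense",
    "Flatten",
    "LeakyReLU",
    "ReLU",
    "Sigmoid",
    "Sequential",
    "Adam",
    "smooth_l1_loss",
]


class Param:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _same_pad(size: int, kernel: int, stride: int) -> tuple[int, int]:
    """Zero-padding (before, after) giving output ceil(size / stride)."""
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    before = total // 2
    return before, total - before


class Conv(Layer):
    """N-dimensional convolution (cross-correlation) with ``same`` padding.

    Input layout is ``(batch, channels, *spatial)``; ``ndim`` spatial axes with
    2 for slices and 3 for volumes.  Weight shape is
    ``(out_channels, in_channels, *kernel)``.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int,
        ndim: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        self.ndim = ndim
        self.stride = stride
        self.kernel = kernel
        kshape = (kernel,) * ndim
        fan_in = in_channels * kernel**ndim
        # He initialization, appropriate for the leaky-rectifier stacks here
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(out_channels, in_channels) + kshape)
        self.w = Param(w.astype(dtype), "conv_w")
        self.b = Param(np.zeros(out_channels, dtype=dtype), "conv_b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        nd, k, s = self.ndim, self.kernel, self.stride
        if x.ndim != nd + 2:
            raise ValueError(
                f"Conv expects (batch, channels, {nd} spatial dims); got shape {x.shape}"
            )
        x = x.astype(self.w.value.dtype, copy=False)
        spatial = x.shape[2:]
        pads = [(0, 0), (0, 0)] + [_same_pad(spatial[i], k, s) for i in range(nd)]
        xp = np.pad(x, pads)
        win = sliding_window_view(xp, (k,) * nd, axis=tuple(range(2, 2 + nd)))
        # stride the output axes
        sl = (slice(None), slice(None)) + (slice(None, None, s),) * nd
        win = win[sl]  # (B, C, *out, *k)
        out_sp = win.shape[2 : 2 + nd]
        B, C = x.shape[:2]
        # (B, *out, C, *k) -> matrix of unrolled receptive fields
        cols = np.moveaxis(win, 1, 1 + nd).reshape(B * int(np.prod(out_sp)), C * k**nd)
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)
        y = cols @ wmat.T + self.b.value
        y = y.reshape((B,) + tuple(out_sp) + (-1,))
        y = np.moveaxis(y, -1, 1)
        self._cache = (cols, x.shape, xp.shape, pads, out_sp)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        nd, k, s = self.ndim, self.kernel, self.stride
        cols, xshape, xpshape, pads, out_sp = self._cache
        B, C = xshape[:2]
        O = self.w.value.shape[0]
        dym = np.moveaxis(dy, 1, -1).reshape(-1, O)
        wmat = self.w.value.reshape(O, -1)
        self.w.grad += (dym.T @ cols).reshape(self.w.value.shape)
        self.b.grad += dym.sum(axis=0)
        dcols = dym @ wmat  # (B*prod(out), C*k^nd)
        dcols = dcols.reshape((B,) + tuple(out_sp) + (C,) + (k,) * nd)
        dxp = np.zeros(xpshape, dtype=cols.dtype)
        # scatter each kernel offset back onto the padded input
        for off in np.ndindex(*(k,) * nd):
            sl_src = (slice(None),) * (1 + nd) + (slice(None),) + off
            block = dcols[sl_src]  # (B, *out, C)
            block = np.moveaxis(block, -1, 1)
            sl_dst = (slice(None), slice(None)) + tuple(
                slice(off[i], off[i] + out_sp[i] * s, s) for i in range(nd)
            )
            dxp[sl_dst] += block
        unpad = (slice(None), slice(None)) + tuple(
            slice(p[0], dxp.shape[2 + i] - p[1]) for i, p in enumerate(pads[2:])
        )
        return dxp[unpad]


class MaxPool(Layer):
    """Non-overlapping max pooling; trailing remainders are dropped (floor)."""

    def __init__(self, pool: Sequence[int]) -> None:
        self.pool = tuple(pool)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pool
        nd = len(p)
        B, C = x.shape[:2]
        sp = x.shape[2:]
        out = tuple(sp[i] // p[i] for i in range(nd))
        if any(o == 0 for o in out):
            raise ValueError(f"MaxPool{p}: input spatial shape {sp} too small")
        crop = (slice(None), slice(None)) + tuple(slice(0, out[i] * p[i]) for i in range(nd))
        xc = x[crop]
        shape = (B, C) + sum(((out[i], p[i]) for i in range(nd)), ())
        xr = xc.reshape(shape)
        # bring the pool axes together at the end
        perm = (0, 1) + tuple(2 + 2 * i for i in range(nd)) + tuple(3 + 2 * i for i in range(nd))
        xt = xr.transpose(perm).reshape((B, C) + out + (int(np.prod(p)),))
        idx = xt.argmax(axis=-1)
        y = np.take_along_axis(xt, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, out)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, xshape, out = self._cache
        p = self.pool
        nd = len(p)
        B, C = xshape[:2]
        dxt = np.zeros((B, C) + out + (int(np.prod(p)),), dtype=dy.dtype)
        np.put_along_axis(dxt, idx[..., None], dy[..., None], axis=-1)
        # invert the transpose/reshape from forward
        dxt = dxt.reshape((B, C) + out + p)
        inv = [0, 1]
        for i in range(nd):
            inv.extend([2 + i, 2 + nd + i])
        dxc = dxt.transpose(inv).reshape((B, C) + tuple(out[i] * p[i] for i in range(nd)))
        dx = np.zeros(xshape, dtype=dy.dtype)
        crop = (slice(None), slice(None)) + tuple(slice(0, out[i] * p[i]) for i in range(nd))
        dx[crop] = dxc
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, dtype=np.float32) -> None:
        limit = math.sqrt(6.0 / (in_features + out_features))
        w = rng.uniform(-limit, limit, size=(in_features, out_features))
        self.w = Param(w.astype(dtype), "dense_w")
        self.b = Param(np.zeros(out_features, dtype=dtype), "dense_b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(self.w.value.dtype, copy=False)
        if x.shape[1] != self.w.value.shape[0]:
            raise ValueError(
                f"Dense expects {self.w.value.shape[0]} features, got {x.shape[1]}"
            )
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01) -> None:
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Sequential:
    """A feed-forward composition of layers with explicit backward."""

    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        params = self.params()
        if len(params) != len(state):
            raise ValueError("parameter count mismatch between networks")
        for p, v in zip(params, state):
            if p.value.shape != v.shape:
                raise ValueError(
                    f"parameter shape mismatch: {p.value.shape} vs {v.shape}"
                )
            p.value[...] = v


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: Sequence[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def smooth_l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Smooth-L1 (Huber, beta=1): mean loss and gradient w.r.t. ``pred``.

    Quadratic within |d| < 1, linear outside — the TD regression loss.
    """
    d = pred - target
    a = np.abs(d)
    quad = a < 1.0
    loss = np.where(quad, 0.5 * d * d, a - 0.5)
    grad = np.where(quad, d, np.sign(d)) / d.size
    return float(loss.mean()), grad
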