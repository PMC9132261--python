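"""Atomic network operations with explicit forward/backward passes.

Tensors are NHWC float32/float64 arrays. Each op caches whatever its backward
pass needs on ``forward`` and exposes ``backward(grad)`` returning the gradient
with respect to its input(s) plus, for parametric ops, gradients stored in
``.grads`` keyed like ``.params``.

The rectifier additionally supports a *guided* backward mode which zeroes the
backward signal wherever either the forward activation or the incoming signal
is non-positive — the rule used by guided backpropagation.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Op",
    "Conv2D",
    "ReLU",
    "MaxPool2D",
    "GlobalAvgPool",
    "Dense",
    "Add",
]


class Op:
    """Base class: single-input op unless stated otherwise."""

    #: number of inputs the op consumes
    arity = 1

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}  # non-trained state

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray, guided: bool = False):  # pragma: no cover
        raise NotImplementedError

    def output_channels(self, in_channels: int) -> int:
        return in_channels


class Conv2D(Op):
    """3x3 (by default) same-padding convolution, stride 1, NHWC layout.

    Weights are stored as (kh, kw, c_in, c_out); bias as (c_out,).
    Forward and backward use im2col via ``sliding_window_view`` + tensordot,
    which keeps everything exact and reasonably fast on CPU.
    """

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        if ksize % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.ksize = c_in, c_out, ksize
        rng = rng or np.random.default_rng(0)
        # He (fan-in scaled) initialization, standard for ReLU networks
        fan_in = ksize * ksize * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(ksize, ksize, c_in, c_out))
        self.params = {"w": w.astype(np.float32), "b": np.zeros(c_out, dtype=np.float32)}

    def output_channels(self, in_channels: int) -> int:
        return self.c_out

    def _pad(self, x: np.ndarray, p: int) -> np.ndarray:
        return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[3] != self.c_in:
            raise ValueError(
                f"expected NHWC input with {self.c_in} channels, got shape {x.shape}"
            )
        p = self.ksize // 2
        xp = self._pad(x, p)
        # windows: (N, H, W, C_in, kh, kw)
        win = sliding_window_view(xp, (self.ksize, self.ksize), axis=(1, 2))
        self._win = win
        self._xshape = x.shape
        w = self.params["w"]
        out = np.tensordot(win, w, axes=([3, 4, 5], [2, 0, 1]))
        out += self.params["b"]
        return out

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        w = self.params["w"]
        # parameter gradients
        dw = np.tensordot(self._win, grad, axes=([0, 1, 2], [0, 1, 2]))  # (C_in,kh,kw,C_out)
        self.grads["w"] = np.transpose(dw, (1, 2, 0, 3))
        self.grads["b"] = grad.sum(axis=(0, 1, 2))
        # input gradient: full correlation of grad with spatially flipped kernel
        p = self.ksize // 2
        gp = self._pad(grad, p)
        gwin = sliding_window_view(gp, (self.ksize, self.ksize), axis=(1, 2))
        wflip = w[::-1, ::-1]  # (kh, kw, C_in, C_out)
        dx = np.tensordot(gwin, wflip, axes=([3, 4, 5], [3, 0, 1]))
        return dx


class BatchNorm(Op):
    """Per-channel batch normalization with learned affine parameters.

    Training mode normalizes with batch statistics and maintains running
    moments; inference mode (the default, and the mode guided backprop sees)
    uses the running moments, so its backward pass is the plain affine
    gradient with the trained scale.
    """

    # momentum 0.5 adapts the running moments within a few minibatches —
    # important when a model is inspected after a single short epoch
    def __init__(self, channels: int, momentum: float = 0.5, eps: float = 1e-5):
        super().__init__()
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        self.buffers = {
            "running_mean": np.zeros(channels, dtype=np.float32),
            "running_var": np.ones(channels, dtype=np.float32),
        }
        self.momentum = momentum
        self.eps = eps
        self.training = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            b = self.buffers
            b["running_mean"] = (self.momentum * b["running_mean"]
                                 + (1 - self.momentum) * mean).astype(np.float32)
            b["running_var"] = (self.momentum * b["running_var"]
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        self._trained_mode = self.training
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        axes = tuple(range(grad.ndim - 1))
        self.grads["gamma"] = (grad * self._xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = self.params["gamma"]
        if not self._trained_mode:
            return grad * g * self._inv_std
        # batch-statistics backward
        m = np.prod([grad.shape[a] for a in axes])
        dxhat = grad * g
        return (self._inv_std / m) * (
            m * dxhat
            - dxhat.sum(axis=axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )


class ReLU(Op):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        if guided:
            return np.where(self._mask & (grad > 0), grad, 0.0)
        return np.where(self._mask, grad, 0.0)


class MaxPool2D(Op):
    """2x2 max pooling, stride 2. Gradient is split evenly among tied maxima."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        out = xt.max(axis=(2, 4))
        self._x = x
        self._xt = xt
        self._out = out
        return out

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        mask = self._xt == self._out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        g = mask * (grad[:, :, None, :, None, :] / counts)
        n, h, w, c = self._x.shape
        dx = np.zeros_like(self._x)
        h2, w2 = h // 2, w // 2
        dx[:, : h2 * 2, : w2 * 2, :] = g.reshape(n, h2 * 2, w2 * 2, c)
        return dx


class GlobalAvgPool(Op):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), self._shape).copy()


class Dense(Op):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.params = {"w": w.astype(np.float32), "b": np.zeros(d_out, dtype=np.float32)}
        self.d_in, self.d_out = d_in, d_out

    def output_channels(self, in_channels: int) -> int:
        return self.d_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        self.grads["w"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["w"].T


class Add(Op):
    """Elementwise sum of two inputs (residual merge)."""

    arity = 2

    def forward(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:  # type: ignore[override]
        if a.shape != b.shape:
            raise ValueError(f"residual add shape mismatch: {a.shape} vs {b.shape}")
        return a + b

    def backward(self, grad: np.ndarray, guided: bool = False):
        return grad, grad
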