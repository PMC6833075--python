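"""Trainable layers with explicit forward/backward passes.

Conventions: activations are separate layers; convolutions are stride-1 with
"same" padding along time; 2D convolutions are "valid" along the (small)
leading modality axis.  Inputs are channels-last: ``(B, L, C)`` for 1D and
``(B, H, L, C)`` for 2D.  Convolutions are evaluated as batched GEMMs on
im2col views, which is where essentially all the compute goes.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv1D",
    "Conv2D",
    "BatchNorm",
    "MaxPool",
    "Dropout",
    "Flatten",
    "Dense",
    "ELU",
]


class Layer:
    """Base layer: ``forward(x, training, rng)`` and ``backward(dy)``."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x, training: bool = False, rng=None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


def _glorot(rng, fan_in: int, fan_out: int, shape, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv1D(Layer):
    """Stride-1 'same' 1D convolution with odd kernel size.

    Evaluated as a sum of k time-shifted batched GEMMs (one per kernel tap),
    which avoids materialising an im2col buffer; a single-input-channel
    layer instead multiplies a sliding-window view directly.  ``Sequential``
    marks the stack's first layer so its (unused) input gradient is skipped.
    """

    is_input_layer = False

    def __init__(self, kernel: int, c_in: int, c_out: int, rng, dtype=np.float32):
        if kernel % 2 != 1:
            raise ValueError("Conv1D requires an odd kernel size for 'same' padding")
        self.k, self.c_in, self.c_out = kernel, c_in, c_out
        self.W = _glorot(rng, kernel * c_in, kernel * c_out, (kernel, c_in, c_out), dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=False, rng=None):
        k, p = self.k, self.k // 2
        B, L, _ = x.shape
        self._xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        if self.c_in == 1:
            win = sliding_window_view(self._xp[:, :, 0], k, axis=1)  # (B, L, k)
            y = win @ self.W[:, 0, :]
        else:
            y = self._xp[:, 0:L] @ self.W[0]
            for j in range(1, k):
                y += self._xp[:, j : j + L] @ self.W[j]
        y += self.b
        return y

    def backward(self, dy):
        k, p = self.k, self.k // 2
        B, L, _ = dy.shape
        if self.c_in == 1:
            win = sliding_window_view(self._xp[:, :, 0], k, axis=1)
            self.dW[...] = np.tensordot(win, dy, axes=([0, 1], [0, 1]))[:, None, :]
        else:
            for j in range(k):
                self.dW[j] = np.tensordot(
                    self._xp[:, j : j + L], dy, axes=([0, 1], [0, 1])
                )
        self.db[...] = dy.sum(axis=(0, 1))
        self._xp = None
        if self.is_input_layer:
            return None
        # dx[m] = sum_o dy_padded[m + o] @ W[k-1-o].T
        dyp = np.pad(dy, ((0, 0), (p, p), (0, 0)))
        WT = self.W.transpose(0, 2, 1)  # (k, c_out, c_in)
        dx = dyp[:, 0:L] @ WT[k - 1]
        for o in range(1, k):
            dx += dyp[:, o : o + L] @ WT[k - 1 - o]
        return dx


class Conv2D(Layer):
    """Stride-1 convolution: 'valid' along rows, 'same' along time.

    Kernel ``(kh, kw)`` with odd ``kw``; a ``(B, H, L, C)`` input maps to
    ``(B, H - kh + 1, L, c_out)``.
    """

    is_input_layer = False

    def __init__(self, kernel: tuple[int, int], c_in: int, c_out: int, rng, dtype=np.float32):
        kh, kw = kernel
        if kw % 2 != 1:
            raise ValueError("Conv2D requires an odd time kernel for 'same' padding")
        self.kh, self.kw, self.c_in, self.c_out = kh, kw, c_in, c_out
        fan = kh * kw
        self.W = _glorot(rng, fan * c_in, fan * c_out, (fan * c_in, c_out), dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    @staticmethod
    def _im2col(x, kh, kw, pad_rows: int):
        # x: (B, H, L, C) -> (B, H', L, kh*kw*C)
        p = kw // 2
        xp = np.pad(x, ((0, 0), (pad_rows, pad_rows), (p, p), (0, 0)))
        win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (B, H', L, C, kh, kw)
        B, Hp, L = win.shape[:3]
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            B * Hp, L, kh * kw * x.shape[-1]
        ), (B, Hp, L)

    def forward(self, x, training=False, rng=None):
        self._xcol, (B, Hp, L) = self._im2col(x, self.kh, self.kw, 0)
        y = self._xcol @ self.W + self.b
        return y.reshape(B, Hp, L, self.c_out)

    def backward(self, dy):
        B, Hp, L, _ = dy.shape
        dyf = dy.reshape(B * Hp, L, self.c_out)
        self.dW[...] = np.tensordot(self._xcol, dyf, axes=([0, 1], [0, 1]))
        self.db[...] = dyf.sum(axis=(0, 1))
        self._xcol = None
        if self.is_input_layer:
            return None
        Wf = np.ascontiguousarray(
            self.W.reshape(self.kh, self.kw, self.c_in, self.c_out)[::-1, ::-1]
            .transpose(0, 1, 3, 2)
        ).reshape(self.kh * self.kw * self.c_out, self.c_in)
        dycol, (B2, H, L2) = self._im2col(dy, self.kh, self.kw, self.kh - 1)
        dx = dycol @ Wf
        return dx.reshape(B2, H, L2, self.c_in)


class BatchNorm(Layer):
    """Per-channel batch normalisation over all leading axes.

    Trainable scale/shift (2 parameters per channel); running statistics
    with momentum 0.9 are used at inference time.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if training:
            n = x.size // x.shape[-1]
            flat = x.reshape(n, x.shape[-1])
            mu = flat.mean(axis=0)
            m2 = np.einsum("nc,nc->c", flat, flat) / n
            var = np.maximum(m2 - mu * mu, 0.0)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mu
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        self._axes = axes
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        axes = self._axes
        self.dgamma[...] = (dy * self._xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        if not self._training:
            return dxhat * self._istd
        m1 = dxhat.mean(axis=axes)
        m2 = (dxhat * self._xhat).mean(axis=axes)
        dx = self._istd * (dxhat - m1 - self._xhat * m2)
        self._xhat = None
        return dx


class MaxPool(Layer):
    """Size-2, stride-2 max pooling along the time axis (second-to-last)."""

    def __init__(self, pool: int = 2):
        if pool != 2:
            raise ValueError("only pool size 2 is supported")
        self.pool = pool

    def forward(self, x, training=False, rng=None):
        L = x.shape[-2]
        L2 = L // 2
        self._in_shape = x.shape
        xr = x[..., : 2 * L2, :].reshape(*x.shape[:-2], L2, 2, x.shape[-1])
        self._idx = xr.argmax(axis=-2)
        return np.take_along_axis(xr, self._idx[..., None, :], axis=-2).squeeze(-2)

    def backward(self, dy):
        L = self._in_shape[-2]
        L2 = L // 2
        g = np.zeros(
            (*self._in_shape[:-2], L2, 2, self._in_shape[-1]), dtype=dy.dtype
        )
        np.put_along_axis(g, self._idx[..., None, :], dy[..., None, :], axis=-2)
        g = g.reshape(*self._in_shape[:-2], 2 * L2, self._in_shape[-1])
        if 2 * L2 < L:
            pad = [(0, 0)] * (g.ndim - 2) + [(0, L - 2 * L2), (0, 0)]
            g = np.pad(g, pad)
        return g


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng, dtype=np.float32):
        self.W = _glorot(rng, n_in, n_out, (n_in, n_out), dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        self._x = None
        return dy @ self.W.T


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, training=False, rng=None):
        neg = x < 0
        y = x.copy()
        y[neg] = self.alpha * np.expm1(x[neg])
        self._neg = neg
        self._y = y
        return y

    def backward(self, dy):
        g = dy.copy()
        neg = self._neg
        g[neg] *= self._y[neg] + self.alpha
        return g
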