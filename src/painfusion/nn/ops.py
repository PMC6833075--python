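"""Elementwise activations and losses."""

from __future__ import annotations

import numpy as np

__all__ = ["elu", "softmax", "cross_entropy"]

_CLIP_EPS = 1e-12


def elu(x, alpha: float = 1.0):
    """Exponential linear unit: ``alpha * (exp(x) - 1)`` for x < 0, else x.

    Continuous at 0 (both branches evaluate to 0).
    """
    x = np.asarray(x)
    return np.where(x >= 0, x, alpha * np.expm1(np.minimum(x, 0.0)))


def softmax(y, axis: int = -1):
    """Overflow-safe softmax: positive components summing to 1 along ``axis``.

    Invariant to adding a constant to all scores.
    """
    y = np.asarray(y, dtype=float)
    z = y - y.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


def cross_entropy(y, y_hat):
    """``-sum_j y_j log(y_hat_j)`` with y one-hot and y_hat clipped to [eps, 1].

    Zero iff ``y_hat`` puts all mass on the true class; averaged over the
    leading axis when given batches.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.clip(np.asarray(y_hat, dtype=float), _CLIP_EPS, 1.0)
    ce = -(y * np.log(y_hat)).sum(axis=-1)
    return float(np.mean(ce))
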