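"""Small numerical primitives shared across modules."""

from __future__ import annotations

import numpy as np


def elu(z: np.ndarray) -> np.ndarray:
    """Exponential linear unit: z for z > 0, exp(z) - 1 otherwise."""
    return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))


def elu_plus_one(z: np.ndarray) -> np.ndarray:
    """ELU offset by one; strictly positive for all finite inputs.

    For very negative z, exp(z) underflows to 0; the result is floored at
    the smallest positive float so the positivity contract survives
    floating-point underflow.
    """
    return np.maximum(elu(z) + 1.0, np.finfo(float).tiny)


def elu_grad(z: np.ndarray) -> np.ndarray:
    """Derivative of ELU (and of ELU + 1)."""
    return np.where(z > 0, 1.0, np.exp(np.minimum(z, 0.0)))


def softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), overflow-safe
    return np.logaddexp(0.0, x)


def softplus_inv(y):
    """Inverse of softplus; y must be > 0."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("softplus_inv requires positive input")
    # x = log(e^y - 1), stable for large y
    return y + np.log(-np.expm1(-y))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(np.asarray(x, dtype=float))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
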