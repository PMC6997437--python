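"""Minimal numpy neural-network primitives shared by the autoencoder and
the pair classifier: seeded fan-in initialisation, activations, binary
cross-entropy, and the classical momentum SGD update

    v <- momentum * v - lr * grad
    w <- w + v

Kept deliberately small: two concrete models with explicit backprop live in
:mod:`mdadti.mda` and :mod:`mdadti.dnn`; there is no autograd.
"""

from __future__ import annotations

import zlib

import numpy as np

# clip sigmoid outputs away from {0,1} before log; keeps BCE finite
_EPS = 1e-12


def derive_seed(seed: int, stage: str) -> int:
    """Stable stage-specific seed below 2**31 from one master seed."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def bce(target: np.ndarray, pred: np.ndarray) -> float:
    """Mean binary cross-entropy over all elements."""
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def init_dense(rng: np.random.Generator, fan_in: int, fan_out: int, gain: float = 1.0):
    """Glorot-uniform weights (bound gain*sqrt(6/(fan_in+fan_out))); zero bias.

    Sigmoid layers use gain=4 (the classical Glorot recommendation for the
    logistic activation); ReLU layers use gain=sqrt(2).
    """
    bound = gain * np.sqrt(6.0 / (fan_in + fan_out))
    W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = np.zeros(fan_out)
    return W, b


def sgd_momentum_step(params, grads, velocities, lr: float, momentum: float) -> None:
    """In-place momentum SGD over parallel flat lists of arrays."""
    for p, g, v in zip(params, grads, velocities):
        v *= momentum
        v -= lr * g
        p += v
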