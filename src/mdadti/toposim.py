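"""Topological featurization of similarity networks: RWR + PPMI.

Each similarity view is treated as a weighted graph.  A random walk with
restart (RWR) is run from every node; the step distributions are accumulated
over T steps into a topological structure feature matrix P, and positive
pointwise mutual information (PPMI) turns P into a nonnegative topological
similarity matrix that encodes the global structure of the network.

The walk recurrence, starting from the one-hot vector p_i(0) of node i on
the row-normalised transition matrix S_hat, is

    p_i(t) = alpha * p_i(t-1) @ S_hat + (1 - alpha) * p_i(0)

and the accumulated feature vector of node i is p_i = sum_{t=1..T} p_i(t).
``alpha`` is the weight of the walk-continuation term (the complement of the
restart mass); every p_i(t) is a probability vector, so row i of the
accumulated matrix sums to T.

PPMI of the accumulated matrix P is

    X[i, k] = max(0, log2( P[i, k] * sum(P) / (rowsum_i * colsum_k) ))

with P[i, k] = 0 mapped to 0 (no -inf is ever formed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_model import SimilaritySet, SimilarityView


class ConfigError(ValueError):
    """Invalid RWR configuration."""


class DegenerateInputError(ValueError):
    """Input matrix carries no usable mass (all zeros)."""


@dataclass(frozen=True)
class RWRConfig:
    """Random-walk-with-restart settings.

    alpha : weight of the walk term in the recurrence, in [0, 1].  At 0 the
        walker never leaves its start node; at 1 there is no restart mass.
    steps : total number of accumulated walk steps T (>= 1).
    """

    alpha: float = 0.9
    steps: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigError(f"alpha must be in [0,1], got {self.alpha}")
        if int(self.steps) != self.steps or self.steps < 1:
            raise ConfigError(f"steps must be an integer >= 1, got {self.steps}")


@dataclass
class TopoFeatureSet:
    """Per-modality topological similarity matrices for one entity kind."""

    entity_kind: str
    labels: list[str]
    matrices: list[np.ndarray]
    scaled: bool

    def __post_init__(self) -> None:
        m = len(self.labels)
        for X in self.matrices:
            if X.shape != (m, m):
                raise ValueError(f"topological matrix shape {X.shape} != ({m},{m})")
            if X.min() < 0:
                raise ValueError("topological matrices must be nonnegative")

    @property
    def n_views(self) -> int:
        return len(self.matrices)


def row_normalize(view: SimilarityView) -> np.ndarray:
    """One-step transition matrix: rows of the similarity matrix scaled to sum 1.

    A row of all zeros (an isolated node) becomes a self-loop so the matrix
    stays row-stochastic.
    """
    S = view.values.copy()
    sums = S.sum(axis=1)
    zero = sums == 0
    if zero.any():
        S[zero, :] = 0.0
        S[zero, zero.nonzero()[0]] = 1.0
        sums = S.sum(axis=1)
    return S / sums[:, None]


def rwr_features(view: SimilarityView, cfg: RWRConfig) -> np.ndarray:
    """Accumulated RWR step distributions, one row per start node.

    Row i equals sum_{t=1..T} p_i(t) of the restart recurrence; it sums to T.
    """
    S_hat = row_normalize(view)
    m = view.n
    eye = np.eye(m)
    p = eye  # p(0): one-hot start vectors stacked as rows
    acc = np.zeros((m, m))
    for _ in range(cfg.steps):
        p = cfg.alpha * (p @ S_hat) + (1.0 - cfg.alpha) * eye
        acc += p
    return acc


def ppmi(P: np.ndarray) -> np.ndarray:
    """Positive pointwise mutual information of a nonnegative matrix.

    Zero entries map to zero; the result is nonnegative and finite.
    """
    P = np.asarray(P, dtype=float)
    if P.min() < 0:
        raise ValueError("ppmi input must be nonnegative")
    total = P.sum()
    if total == 0:
        raise DegenerateInputError("ppmi input is all zeros")
    rows = P.sum(axis=1)
    cols = P.sum(axis=0)
    X = np.zeros_like(P)
    i, k = np.nonzero(P)  # margins are > 0 wherever P is
    X[i, k] = np.maximum(0.0, np.log2(P[i, k] * total / (rows[i] * cols[k])))
    return X


def minmax_scale(X: np.ndarray) -> np.ndarray:
    """Scale a matrix to [0,1] by its global min/max; constant matrices map to 0."""
    lo, hi = X.min(), X.max()
    if hi == lo:
        return np.zeros_like(X)
    return (X - lo) / (hi - lo)


def topologize(sims: SimilaritySet, cfg: RWRConfig, scale: bool = True) -> TopoFeatureSet:
    """RWR + PPMI per view, optionally min-max scaled to [0,1].

    Scaling is on by default because the downstream autoencoder reconstructs
    these matrices through sigmoid outputs under a cross-entropy loss, which
    needs targets in [0,1]; raw PPMI is unbounded above.
    """
    mats = []
    for view in sims.views:
        X = ppmi(rwr_features(view, cfg))
        if scale:
            X = minmax_scale(X)
        mats.append(X)
    return TopoFeatureSet(
        entity_kind=sims.entity_kind,
        labels=list(sims.labels),
        matrices=mats,
        scaled=scale,
    )
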