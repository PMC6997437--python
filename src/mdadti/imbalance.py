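"""SMOTE oversampling of the minority (positive) class in pair-feature space.

Known drug-target interactions are rare relative to unknown pairs, so the
training folds are heavily imbalanced.  SMOTE synthesises new minority rows
on the segment between a minority row and one of its k nearest minority
neighbours:

    x_new = x_i + u * (x_nn - x_i),    u ~ Uniform(0, 1)

Oversampling is applied only to the training portion of a fold, never to
test pairs.  Synthetic rows carry the pair index (-1, -1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .dnn import PairDataset


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    target_ratio: float = 1.0  # minority:majority ratio after oversampling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be positive")


def smote(train: PairDataset, cfg: SmoteConfig) -> PairDataset:
    """Oversample the minority class to `target_ratio` x majority count.

    Original rows are preserved unchanged (synthetic rows are appended);
    deterministic for a fixed seed.
    """
    if train.labels is None:
        raise ValueError("smote requires labels")
    y = train.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("smote requires both classes present")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min <= cfg.k_neighbors:
        raise ValueError(
            f"minority count {n_min} must exceed k_neighbors={cfg.k_neighbors}; lower k"
        )
    n_new = int(round(cfg.target_ratio * n_maj)) - n_min
    if n_new <= 0:
        return train

    X_min = train.features[y == minority]
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(X_min)
    # drop the self-neighbour in column 0
    neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, len(X_min), size=n_new)
    pick = rng.integers(0, cfg.k_neighbors, size=n_new)
    u = rng.random(n_new)
    x_i = X_min[base]
    x_nn = X_min[neigh[base, pick]]
    synth = x_i + u[:, None] * (x_nn - x_i)

    return PairDataset(
        pairs=np.concatenate([train.pairs, np.full((n_new, 2), -1, dtype=int)]),
        features=np.concatenate([train.features, synth]),
        labels=np.concatenate([train.labels, np.full(n_new, minority, dtype=np.int8)]),
    )
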