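"""Ranking of unknown drug-target pairs by predicted interaction probability.

Only pairs with y = 0 (unknown, not confirmed negative) are scored; known
interactions never appear in the output.  Pairs are sorted by probability
descending, with ties broken deterministically by (drug label, target label)
lexicographic order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dnn import DNNModel, make_pairs, predict_proba

logger = logging.getLogger("mdadti")


@dataclass(frozen=True)
class RankedPair:
    rank: int
    drug: str
    target: str
    probability: float


def rank_unknown(
    model: DNNModel,
    H_d: np.ndarray,
    H_t: np.ndarray,
    Y: np.ndarray,
    top_n: int,
    drug_labels: list[str] | None = None,
    target_labels: list[str] | None = None,
) -> list[RankedPair]:
    """Top-`top_n` unknown pairs by descending predicted probability."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    Y = np.asarray(Y)
    n_d, n_t = Y.shape
    if drug_labels is None:
        drug_labels = [f"d{i}" for i in range(n_d)]
    if target_labels is None:
        target_labels = [f"t{j}" for j in range(n_t)]
    unknown = np.argwhere(Y == 0)
    if len(unknown) == 0:
        logger.warning("no unknown pairs to rank")
        return []
    ds = make_pairs(H_d, H_t, None, unknown)
    probs = predict_proba(model, ds.features)
    order = sorted(
        range(len(unknown)),
        key=lambda k: (-probs[k], drug_labels[unknown[k, 0]], target_labels[unknown[k, 1]]),
    )
    out = []
    for rank, k in enumerate(order[: min(top_n, len(unknown))], start=1):
        i, j = unknown[k]
        out.append(
            RankedPair(
                rank=rank,
                drug=drug_labels[i],
                target=target_labels[j],
                probability=float(probs[k]),
            )
        )
    return out
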