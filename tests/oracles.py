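"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the RWR oracle uses
explicit matrix powers of the closed-form expansion, and the AUC/AUPR
oracles enumerate pairs / sweep thresholds directly.
"""

from __future__ import annotations

import numpy as np


def rwr_closed_form(S_hat: np.ndarray, alpha: float, steps: int) -> np.ndarray:
    """Accumulated walk distributions via the matrix-power expansion

    p(t) = alpha^t S^t + (1 - alpha) * sum_{k=0}^{t-1} alpha^k S^k
    acc  = sum_{t=1..T} p(t),   starting from the identity (one row per node).
    """
    m = S_hat.shape[0]
    acc = np.zeros((m, m))
    for t in range(1, steps + 1):
        p_t = (alpha**t) * np.linalg.matrix_power(S_hat, t)
        for k in range(t):
            p_t += (1.0 - alpha) * (alpha**k) * np.linalg.matrix_power(S_hat, k)
        acc += p_t
    return acc


def rwr_step_distributions(S_hat: np.ndarray, alpha: float, steps: int) -> list[np.ndarray]:
    """The individual p(t) matrices of the recurrence, computed iteratively."""
    m = S_hat.shape[0]
    p = np.eye(m)
    out = []
    for _ in range(steps):
        p = alpha * (p @ S_hat) + (1.0 - alpha) * np.eye(m)
        out.append(p.copy())
    return out


def auc_bruteforce(labels, scores) -> float:
    """Mann-Whitney statistic by explicit enumeration; ties count 1/2."""
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def aupr_bruteforce(labels, scores) -> float:
    """Area under the precision-recall step curve by exhaustive threshold sweep
    from the highest score down (no interpolation)."""
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    n_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    for thr in sorted(set(scores), reverse=True):
        pred = scores >= thr
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area
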