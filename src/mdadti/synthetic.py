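"""Seeded generator of desk-scale synthetic datasets with the statistical
structure the method assumes: multiple noisy similarity views of a shared
cluster structure, and interactions concentrated between matched drug and
target clusters (guilt by association - similar drugs tend to share similar
targets), with a low background rate elsewhere so the data are imbalanced.

Each view's entries are clamp_[0,1](base + noise) where base is within_sim
for same-cluster pairs and between_sim otherwise, shifted by a small
per-view offset common to both levels (so views carry complementary,
independently noisy copies of the same structure); views are symmetrised
and given a unit diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import derive_seed
from .dataset_model import (
    Dataset,
    InteractionMatrix,
    SimilaritySet,
    SimilarityView,
    assemble_dataset,
)


@dataclass(frozen=True)
class SynthConfig:
    n_drugs: int = 60
    n_targets: int = 40
    k_drug_clusters: int = 3
    k_target_clusters: int = 3
    n_drug_views: int = 3
    n_target_views: int = 3
    within_sim: float = 0.8
    between_sim: float = 0.2
    view_noise_sd: float = 0.05
    view_base_jitter_sd: float = 0.03  # per-view offset applied to both levels
    matched_rate: float = 0.6  # interaction prob for matched cluster pairs
    background_rate: float = 0.02
    interaction_map: dict | None = None  # (drug_cluster, target_cluster) -> prob
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.within_sim >= self.between_sim):
            raise ValueError("within_sim must be >= between_sim")
        for p in (self.within_sim, self.between_sim, self.matched_rate, self.background_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probabilities must be in [0,1], got {p}")
        if min(self.n_drugs, self.n_targets, self.k_drug_clusters, self.k_target_clusters) < 1:
            raise ValueError("counts must be >= 1")

    def rate_for(self, drug_cluster: int, target_cluster: int) -> float:
        if self.interaction_map is not None:
            return self.interaction_map.get((drug_cluster, target_cluster), self.background_rate)
        return self.matched_rate if drug_cluster == target_cluster else self.background_rate


def _make_views(
    rng: np.random.Generator,
    clusters: np.ndarray,
    cfg: SynthConfig,
    n_views: int,
    prefix: str,
) -> list[SimilarityView]:
    m = len(clusters)
    same = clusters[:, None] == clusters[None, :]
    views = []
    for v in range(n_views):
        offset = rng.normal(0.0, cfg.view_base_jitter_sd)
        base = np.where(same, cfg.within_sim + offset, cfg.between_sim + offset)
        noise = rng.normal(0.0, cfg.view_noise_sd, size=(m, m))
        noise = (noise + noise.T) / 2.0
        mat = np.clip(base + noise, 0.0, 1.0)
        mat = (mat + mat.T) / 2.0
        np.fill_diagonal(mat, 1.0)
        labels = [f"{prefix}{i}" for i in range(m)]
        views.append(SimilarityView(name=f"{prefix}view{v}", labels=labels, values=mat))
    return views


def generate(cfg: SynthConfig) -> tuple[Dataset, dict[str, np.ndarray]]:
    """Deterministic synthetic dataset plus the ground-truth cluster labels."""
    rng = np.random.default_rng(derive_seed(cfg.seed, "synth"))
    drug_clusters = rng.integers(0, cfg.k_drug_clusters, size=cfg.n_drugs)
    target_clusters = rng.integers(0, cfg.k_target_clusters, size=cfg.n_targets)
    drug_views = _make_views(rng, drug_clusters, cfg, cfg.n_drug_views, "d")
    target_views = _make_views(rng, target_clusters, cfg, cfg.n_target_views, "t")
    rates = np.array(
        [
            [cfg.rate_for(dc, tc) for tc in target_clusters]
            for dc in drug_clusters
        ]
    )
    y = (rng.random((cfg.n_drugs, cfg.n_targets)) < rates).astype(np.int8)
    dataset = assemble_dataset(
        SimilaritySet(entity_kind="drug", views=drug_views),
        SimilaritySet(entity_kind="target", views=target_views),
        InteractionMatrix(
            drug_labels=[f"d{i}" for i in range(cfg.n_drugs)],
            target_labels=[f"t{j}" for j in range(cfg.n_targets)],
            y=y,
        ),
    )
    return dataset, {"drug": drug_clusters, "target": target_clusters}


def expected_positive_rate(cfg: SynthConfig, clusters: dict[str, np.ndarray]) -> float:
    """Expectation of mean(Y) given the realised cluster assignments."""
    rates = np.array(
        [[cfg.rate_for(dc, tc) for tc in clusters["target"]] for dc in clusters["drug"]]
    )
    return float(rates.mean())
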