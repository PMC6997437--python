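import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mdadti import (
    DNNConfig,
    LayerConfig,
    MDATrainConfig,
    ModelConfigs,
    RWRConfig,
    SimilaritySet,
    SimilarityView,
    SynthConfig,
    extract_features,
    generate,
)


def random_similarity_view(rng: np.random.Generator, m: int, name: str = "v") -> SimilarityView:
    vals = rng.random((m, m))
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 1.0)
    return SimilarityView(name=name, labels=[f"e{i}" for i in range(m)], values=vals)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted dataset for fast structural tests (20 drugs x 15 targets)."""
    cfg = SynthConfig(
        n_drugs=20, n_targets=15, k_drug_clusters=2, k_target_clusters=2,
        n_drug_views=2, n_target_views=2, seed=7,
    )
    dataset, clusters = generate(cfg)
    return dataset, clusters, cfg


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-condition dataset: 60 drugs, 40 targets, 3+3 views,
    3x3 clusters, matched-cluster interaction rate 0.6 over background 0.02."""
    cfg = SynthConfig(seed=1)
    dataset, clusters = generate(cfg)
    return dataset, clusters, cfg


def synth_model_configs(dataset, seed: int = 11, dropout_p: float = 0.2) -> ModelConfigs:
    """Evaluation configuration used for the synthetic datasets.

    Dropout is reduced from the benchmark-scale default of 0.5 to 0.2: at a
    few thousand training pairs the heavier rate under-trains within the
    patience-10 early-stopping budget.
    """
    return ModelConfigs(
        rwr=RWRConfig(),
        drug_layers=LayerConfig(dataset.drug_sims.n_views, dataset.n_drugs, (), 50),
        target_layers=LayerConfig(dataset.target_sims.n_views, dataset.n_targets, (), 25),
        mda_train=MDATrainConfig(rng_seed=seed),
        dnn=DNNConfig(seed=seed + 1, dropout_p=dropout_p),
    )


@pytest.fixture(scope="session")
def default_features(default_dataset):
    """Unsupervised fused features of the default dataset, shared across tests."""
    dataset, _, _ = default_dataset
    mc = synth_model_configs(dataset)
    return extract_features(
        dataset, mc.drug_layers, mc.target_layers, mc.rwr, mc.mda_train
    )
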