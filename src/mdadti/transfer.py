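"""Transfer learning for small datasets: pretrain the pair classifier on a
large source dataset, freeze every layer except the output unit, and
finetune that single layer on the small target dataset.

Both datasets get their own freshly trained feature extractors, at identical
bottleneck widths so the pair-feature dimension matches; only the classifier
weights transfer.  For the default 300/200/100 architecture the finetuning
stage trains exactly 100 weights + 1 bias = 101 parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import derive_seed
from .dataset_model import Dataset
from .dnn import DNNConfig, DNNModel, make_pairs, train_dnn
from .imbalance import SmoteConfig, smote
from .mda import LayerConfig, MDATrainConfig, extract_features
from .toposim import RWRConfig


@dataclass(frozen=True)
class TransferConfig:
    """Shared settings for the pretrain + finetune run.

    Branch widths / bottlenecks apply to BOTH datasets' extractors so the
    concatenated pair-feature dimension lines up.
    """

    rwr: RWRConfig
    mda_train: MDATrainConfig
    dnn: DNNConfig
    drug_branch: tuple[int, ...] = ()
    drug_bottleneck: int = 50
    target_branch: tuple[int, ...] = ()
    target_bottleneck: int = 25
    smote: SmoteConfig | None = None


@dataclass
class TransferResult:
    model: DNNModel  # finetuned classifier
    source_model: DNNModel  # pretrained classifier (before finetuning)
    target_H_d: np.ndarray
    target_H_t: np.ndarray


def _all_pairs(n_d: int, n_t: int) -> np.ndarray:
    return np.array([(i, j) for i in range(n_d) for j in range(n_t)], dtype=int)


def _features_for(dataset: Dataset, cfg: TransferConfig, seed: int):
    drug_cfg = LayerConfig(
        dataset.drug_sims.n_views, dataset.n_drugs, cfg.drug_branch, cfg.drug_bottleneck
    )
    target_cfg = LayerConfig(
        dataset.target_sims.n_views, dataset.n_targets, cfg.target_branch, cfg.target_bottleneck
    )
    mda_cfg = MDATrainConfig(
        epochs=cfg.mda_train.epochs,
        batch_size=cfg.mda_train.batch_size,
        learning_rate=cfg.mda_train.learning_rate,
        momentum=cfg.mda_train.momentum,
        rng_seed=seed,
    )
    return extract_features(dataset, drug_cfg, target_cfg, cfg.rwr, mda_cfg)


def _training_set(dataset: Dataset, H_d, H_t, cfg: TransferConfig, seed: int):
    pairs = _all_pairs(dataset.n_drugs, dataset.n_targets)
    ds = make_pairs(H_d, H_t, dataset.interactions.y, pairs)
    if cfg.smote is not None:
        ds = smote(
            ds,
            SmoteConfig(
                k_neighbors=cfg.smote.k_neighbors,
                target_ratio=cfg.smote.target_ratio,
                seed=derive_seed(seed, "transfer-smote"),
            ),
        )
    return ds


def pretrain_finetune(
    source: Dataset, target: Dataset, configs: TransferConfig, seed: int
) -> TransferResult:
    """Pretrain on all of `source`, freeze hidden layers, finetune the
    reinitialised output layer on all of `target`.

    Frozen parameters are bitwise identical before and after finetuning.
    """
    src_Hd, src_Ht = _features_for(source, configs, derive_seed(seed, "transfer-src-mda"))
    tgt_Hd, tgt_Ht = _features_for(target, configs, derive_seed(seed, "transfer-tgt-mda"))
    if src_Hd.shape[1] + src_Ht.shape[1] != tgt_Hd.shape[1] + tgt_Ht.shape[1]:
        raise ValueError(
            "source and target pair-feature dimensions differ; align the bottleneck widths"
        )

    dnn = configs.dnn
    src_cfg = DNNConfig(
        hidden_widths=dnn.hidden_widths,
        dropout_p=dnn.dropout_p,
        momentum=dnn.momentum,
        learning_rate=dnn.learning_rate,
        max_epochs=dnn.max_epochs,
        patience=dnn.patience,
        val_fraction=dnn.val_fraction,
        batch_size=dnn.batch_size,
        seed=derive_seed(seed, "transfer-pretrain"),
    )
    src_train = _training_set(source, src_Hd, src_Ht, configs, derive_seed(seed, "src-data"))
    source_model = train_dnn(src_train, src_cfg)

    finetuned = DNNModel(source_model.input_dim, src_cfg)
    finetuned.set_weights(source_model.copy_weights())
    finetuned.reinit_output_layer(derive_seed(seed, "transfer-reinit"))
    finetuned.trainable = [False] * (len(finetuned.layers) - 1) + [True]

    tgt_train = _training_set(target, tgt_Hd, tgt_Ht, configs, derive_seed(seed, "tgt-data"))
    ft_cfg = DNNConfig(
        hidden_widths=dnn.hidden_widths,
        dropout_p=dnn.dropout_p,
        momentum=dnn.momentum,
        learning_rate=dnn.learning_rate,
        max_epochs=dnn.max_epochs,
        patience=dnn.patience,
        val_fraction=dnn.val_fraction,
        batch_size=dnn.batch_size,
        seed=derive_seed(seed, "transfer-finetune"),
    )
    train_dnn(tgt_train, ft_cfg, model=finetuned)
    return TransferResult(
        model=finetuned, source_model=source_model, target_H_d=tgt_Hd, target_H_t=tgt_Ht
    )
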