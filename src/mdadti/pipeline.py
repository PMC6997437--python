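"""End-to-end orchestration from one YAML manifest: dataset (files or
synthetic) -> topological features -> autoencoder fusion -> classifier ->
cross-validated evaluation and/or ranking of unknown pairs.

One global seed fans out into stage-specific seeds by stable hashing of the
stage name, so any stage can be rerun in isolation; rerunning the same
manifest reproduces every output bit for bit.  The effective value of every
parameter (including defaults the user never set) and every derived seed is
written to `run_manifest.yaml` in the output directory.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import yaml

from ._nn import derive_seed
from .dataset_model import (
    Dataset,
    SimilaritySet,
    assemble_dataset,
    read_interactions,
    read_similarity_view,
)
from .dnn import DNNConfig, make_pairs, train_dnn
from .evaluation import CVResult, ModelConfigs, audit_plan, make_cv_plan, run_cv
from .imbalance import SmoteConfig, smote
from .mda import LayerConfig, MDATrainConfig, extract_features
from .ranking import rank_unknown
from .synthetic import SynthConfig, generate
from .toposim import RWRConfig

logger = logging.getLogger("mdadti")


class ManifestError(ValueError):
    """Unknown or missing manifest keys (the schema is strict)."""


_SCHEMA: dict[str, set] = {
    "": {"seed", "out_dir", "dataset", "rwr", "mda", "dnn", "smote", "evaluate", "rank"},
    "dataset": {"synth", "files"},
    "dataset.files": {"drugs", "targets", "interactions"},
    "rwr": {"alpha", "steps"},
    "mda": {
        "drug_branch",
        "drug_bottleneck",
        "target_branch",
        "target_bottleneck",
        "epochs",
        "batch_size",
        "learning_rate",
        "momentum",
    },
    "dnn": {
        "hidden_widths",
        "dropout_p",
        "momentum",
        "learning_rate",
        "max_epochs",
        "patience",
        "val_fraction",
        "batch_size",
    },
    "smote": {"enabled", "k_neighbors", "target_ratio"},
    "evaluate": {"setting", "folds", "repeats", "shuffle_labels"},
    "rank": {"top_n"},
}

_SYNTH_KEYS = {f.name for f in dataclasses.fields(SynthConfig)}


def _check_keys(d: dict, section: str) -> dict:
    allowed = _SCHEMA[section] if section != "dataset.synth" else _SYNTH_KEYS
    unknown = set(d) - allowed
    if unknown:
        raise ManifestError(f"unknown key(s) {sorted(unknown)} in section {section or 'root'}")
    return d


def load_manifest(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = path_or_dict
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ManifestError("manifest must be a mapping")
    _check_keys(cfg, "")
    for sec in ("dataset", "rwr", "mda", "dnn", "smote", "evaluate", "rank"):
        if sec in cfg and cfg[sec] is not None:
            _check_keys(cfg[sec], sec)
    ds = cfg.get("dataset", {})
    if "synth" in ds and ds["synth"] is not None:
        _check_keys(ds["synth"], "dataset.synth")
    if "files" in ds and ds["files"] is not None:
        _check_keys(ds["files"], "dataset.files")
    return cfg


def load_dataset_from_files(files: dict, base_dir: Path | None = None) -> Dataset:
    """Dataset from a manifest `files` section: modality name -> path maps
    for drugs and targets, plus the interaction matrix path."""
    base = Path(base_dir) if base_dir else Path(".")
    resolve = lambda p: p if Path(p).is_absolute() else str(base / p)
    drug_views = [
        read_similarity_view(resolve(p), name) for name, p in files["drugs"].items()
    ]
    target_views = [
        read_similarity_view(resolve(p), name) for name, p in files["targets"].items()
    ]
    interactions = read_interactions(resolve(files["interactions"]))
    return assemble_dataset(
        SimilaritySet(entity_kind="drug", views=drug_views),
        SimilaritySet(entity_kind="target", views=target_views),
        interactions,
    )


def resolve_configs(cfg: dict, dataset: Dataset, seed: int):
    """Effective (ModelConfigs, SmoteConfig | None) from a validated manifest."""
    rwr_d = cfg.get("rwr") or {}
    rwr = RWRConfig(alpha=rwr_d.get("alpha", 0.9), steps=rwr_d.get("steps", 10))
    mda_d = cfg.get("mda") or {}
    drug_layers = LayerConfig(
        dataset.drug_sims.n_views,
        dataset.n_drugs,
        tuple(mda_d.get("drug_branch", ()) or ()),
        mda_d.get("drug_bottleneck", 50),
    )
    target_layers = LayerConfig(
        dataset.target_sims.n_views,
        dataset.n_targets,
        tuple(mda_d.get("target_branch", ()) or ()),
        mda_d.get("target_bottleneck", 25),
    )
    mda_train = MDATrainConfig(
        epochs=mda_d.get("epochs", 100),
        batch_size=mda_d.get("batch_size", 32),
        learning_rate=mda_d.get("learning_rate", 0.001),
        momentum=mda_d.get("momentum", 0.9),
        rng_seed=derive_seed(seed, "features"),
    )
    dnn_d = cfg.get("dnn") or {}
    dnn = DNNConfig(
        hidden_widths=tuple(dnn_d.get("hidden_widths", (300, 200, 100))),
        dropout_p=dnn_d.get("dropout_p", 0.5),
        momentum=dnn_d.get("momentum", 0.9),
        learning_rate=dnn_d.get("learning_rate", 0.01),
        max_epochs=dnn_d.get("max_epochs", 200),
        patience=dnn_d.get("patience", 10),
        val_fraction=dnn_d.get("val_fraction", 0.1),
        batch_size=dnn_d.get("batch_size", 32),
        seed=derive_seed(seed, "dnn"),
    )
    smote_d = cfg.get("smote") or {}
    smote_cfg = None
    if smote_d.get("enabled", True):
        smote_cfg = SmoteConfig(
            k_neighbors=smote_d.get("k_neighbors", 5),
            target_ratio=smote_d.get("target_ratio", 1.0),
            seed=derive_seed(seed, "smote"),
        )
    return ModelConfigs(rwr, drug_layers, target_layers, mda_train, dnn), smote_cfg


def _fmt(x) -> str:
    return repr(float(x)) if isinstance(x, (float, np.floating)) else str(x)


def write_cv_results(result: CVResult, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\trepeat\tfold\tn_test\tauc\taupr\n")
        for rec in result.fold_records:
            fh.write(
                "fold\t{repeat}\t{fold}\t{n_test}\t{auc}\t{aupr}\n".format(
                    repeat=rec["repeat"],
                    fold=rec["fold"],
                    n_test=rec["n_test"],
                    auc=_fmt(rec["auc"]) if "auc" in rec else "NA",
                    aupr=_fmt(rec["aupr"]) if "aupr" in rec else "NA",
                )
            )
        for r, (a, p) in enumerate(zip(result.per_repeat_auc, result.per_repeat_aupr)):
            fh.write(f"repeat\t{r}\t\t\t{_fmt(a)}\t{_fmt(p)}\n")
        fh.write(f"final\t\t\t\t{_fmt(result.mean_auc)}\t{_fmt(result.mean_aupr)}\n")


def run_pipeline(config, out_dir=None, base_dir=None) -> Path:
    """Execute the manifest end to end; returns the output directory."""
    cfg = load_manifest(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "mdadti_results"))
    out.mkdir(parents=True, exist_ok=True)

    ds_cfg = cfg.get("dataset") or {}
    if "synth" in ds_cfg and ds_cfg["synth"] is not None:
        synth_cfg = SynthConfig(**{**ds_cfg["synth"], "seed": ds_cfg["synth"].get("seed", derive_seed(seed, "synth"))})
        dataset, _ = generate(synth_cfg)
    elif "files" in ds_cfg and ds_cfg["files"] is not None:
        dataset = load_dataset_from_files(ds_cfg["files"], base_dir)
    else:
        raise ManifestError("dataset section must provide 'synth' or 'files'")

    configs, smote_cfg = resolve_configs(cfg, dataset, seed)
    H_d, H_t = extract_features(
        dataset, configs.drug_layers, configs.target_layers, configs.rwr, configs.mda_train
    )

    effective = {
        "seed": seed,
        "stage_seeds": {
            s: derive_seed(seed, s) for s in ("synth", "features", "dnn", "smote", "cv")
        },
        "rwr": {"alpha": configs.rwr.alpha, "steps": configs.rwr.steps},
        "mda": {
            "drug_branch": list(configs.drug_layers.branch_widths),
            "drug_bottleneck": configs.drug_layers.bottleneck,
            "target_branch": list(configs.target_layers.branch_widths),
            "target_bottleneck": configs.target_layers.bottleneck,
            "epochs": configs.mda_train.epochs,
            "batch_size": configs.mda_train.batch_size,
            "learning_rate": configs.mda_train.learning_rate,
            "momentum": configs.mda_train.momentum,
        },
        "dnn": {
            "hidden_widths": list(configs.dnn.hidden_widths),
            "dropout_p": configs.dnn.dropout_p,
            "momentum": configs.dnn.momentum,
            "learning_rate": configs.dnn.learning_rate,
            "max_epochs": configs.dnn.max_epochs,
            "patience": configs.dnn.patience,
            "val_fraction": configs.dnn.val_fraction,
            "batch_size": configs.dnn.batch_size,
        },
        "smote": None
        if smote_cfg is None
        else {"k_neighbors": smote_cfg.k_neighbors, "target_ratio": smote_cfg.target_ratio},
    }

    ev = cfg.get("evaluate")
    if ev is not None:
        setting = ev.get("setting", "CVS1")
        plan = make_cv_plan(
            dataset,
            setting,
            seed=derive_seed(seed, "cv"),
            n_folds=ev.get("folds", 10),
            n_repeats=ev.get("repeats", 5),
        )
        violations = audit_plan(plan, dataset)
        shuffle_seed = derive_seed(seed, "null") if ev.get("shuffle_labels", False) else None
        result = run_cv(
            dataset, plan, configs, smote_cfg, features=(H_d, H_t), shuffle_labels_seed=shuffle_seed
        )
        write_cv_results(result, out / "results.tsv")
        with open(out / "leakage_audit.txt", "w") as fh:
            fh.write(f"setting\t{setting}\nviolations\t{violations}\n")
        effective["evaluate"] = {
            "setting": setting,
            "folds": plan.n_folds,
            "repeats": plan.n_repeats,
            "shuffle_labels": bool(ev.get("shuffle_labels", False)),
            "leakage_violations": violations,
        }

    rk = cfg.get("rank")
    if rk is not None:
        Y = dataset.interactions.y
        all_pairs = np.argwhere(np.ones_like(Y, dtype=bool))
        train_ds = make_pairs(H_d, H_t, Y, all_pairs)
        if smote_cfg is not None:
            train_ds = smote(train_ds, smote_cfg)
        model = train_dnn(train_ds, configs.dnn)
        top = rank_unknown(
            model,
            H_d,
            H_t,
            Y,
            rk.get("top_n", 100),
            drug_labels=dataset.drug_sims.labels,
            target_labels=dataset.target_sims.labels,
        )
        with open(out / "ranking.tsv", "w") as fh:
            fh.write("rank\tdrug\ttarget\tprobability\n")
            for rp in top:
                fh.write(f"{rp.rank}\t{rp.drug}\t{rp.target}\t{_fmt(rp.probability)}\n")
        effective["rank"] = {"top_n": rk.get("top_n", 100)}

    with open(out / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(effective, fh, sort_keys=True)
    return out
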