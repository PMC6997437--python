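"""Cross-validation harness: blinded fold plans, ranking metrics, and the
bootstrap paired t-test.

Three blinding settings model three prediction tasks:

* CVS1 - hold out random drug-target PAIRS (new pairs); stratified by label.
* CVS2 - hold out whole DRUGS (matrix rows; new drugs).
* CVS3 - hold out whole TARGETS (matrix columns; new targets).

The protocol is n_repeats repeats of n_folds-fold cross-validation (default
5 x 10).  Entity features come from the unsupervised autoencoder stage,
computed once per dataset and reused across folds (the feature extractor
never reads Y, so folds stay leak-free); only the supervised classifier
respects fold boundaries.  Each repeat's AUC/AUPR is computed over the
pooled predictions of its folds; the final score averages the repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from ._nn import derive_seed
from .dataset_model import Dataset
from .dnn import DNNConfig, PairDataset, make_pairs, predict_proba, train_dnn
from .imbalance import SmoteConfig, smote
from .mda import LayerConfig, MDATrainConfig, extract_features
from .toposim import RWRConfig

logger = logging.getLogger("mdadti")

SETTINGS = ("CVS1", "CVS2", "CVS3")


@dataclass
class CVPlan:
    """Fold assignments for one blinding setting.

    assignments[r][f] is the array of held-out unit indices of fold f in
    repeat r: flat pair indices (drug * n_targets + target) for CVS1, drug
    indices for CVS2, target indices for CVS3.
    """

    setting: str
    n_folds: int
    n_repeats: int
    assignments: list[list[np.ndarray]]
    seed: int

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}")


@dataclass
class CVResult:
    setting: str
    per_repeat_auc: list[float]
    per_repeat_aupr: list[float]
    fold_records: list[dict]
    skipped_folds: list[tuple[int, int, str]]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_repeat_auc))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.per_repeat_aupr))


@dataclass(frozen=True)
class ModelConfigs:
    """Everything run_cv needs besides the data and the fold plan."""

    rwr: RWRConfig
    drug_layers: LayerConfig
    target_layers: LayerConfig
    mda_train: MDATrainConfig
    dnn: DNNConfig


def make_cv_plan(
    dataset: Dataset,
    setting: str,
    seed: int,
    n_folds: int = 10,
    n_repeats: int = 5,
) -> CVPlan:
    """Fold plan for one setting; each repeat reshuffles with a derived seed."""
    if setting not in SETTINGS:
        raise ValueError(f"setting must be one of {SETTINGS}")
    n_d, n_t = dataset.n_drugs, dataset.n_targets
    if setting == "CVS1":
        n_units = n_d * n_t
        strat = dataset.interactions.y.ravel()
    elif setting == "CVS2":
        n_units, strat = n_d, None
    else:
        n_units, strat = n_t, None
    if n_units < n_folds:
        raise ValueError(f"{n_units} units cannot fill {n_folds} folds")
    assignments = []
    for r in range(n_repeats):
        rs = derive_seed(seed, f"cvplan-{setting}-rep{r}") % (2**32)
        if strat is not None:
            splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
            folds = [test for _, test in splitter.split(np.zeros(n_units), strat)]
        else:
            splitter = KFold(n_splits=n_folds, shuffle=True, random_state=rs)
            folds = [test for _, test in splitter.split(np.zeros(n_units))]
        assignments.append(folds)
    return CVPlan(
        setting=setting, n_folds=n_folds, n_repeats=n_repeats, assignments=assignments, seed=seed
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

UNDEFINED = float("nan")  # marker for a metric with a zero denominator


@dataclass(frozen=True)
class ConfusionMetrics:
    tpr: float  # = recall
    fpr: float
    precision: float

    @property
    def recall(self) -> float:
        return self.tpr


def confusion_metrics(labels, predictions) -> ConfusionMetrics:
    """TPR/recall, FPR and precision from binary labels and decisions.

    A zero denominator yields the NaN undefined-marker, never 0.
    """
    y = np.asarray(labels).astype(int).ravel()
    p = np.asarray(predictions).astype(int).ravel()
    if len(y) != len(p):
        raise ValueError("labels and predictions must have equal length")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    tn = int(np.sum((y == 0) & (p == 0)))
    tpr = tp / (tp + fn) if tp + fn else UNDEFINED
    fpr = fp / (fp + tn) if fp + tn else UNDEFINED
    prec = tp / (tp + fp) if tp + fp else UNDEFINED
    return ConfusionMetrics(tpr=tpr, fpr=fpr, precision=prec)


def auc(labels, scores) -> float:
    """Area under the ROC curve (Mann-Whitney statistic; ties count 1/2)."""
    y = np.asarray(labels).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores).ravel()))


def aupr(labels, scores) -> float:
    """Area under the precision-recall step curve (no interpolation)."""
    y = np.asarray(labels).ravel()
    if y.sum() < 1:
        raise ValueError("AUPR needs at least one positive")
    return float(average_precision_score(y, np.asarray(scores).ravel()))


# ---------------------------------------------------------------------------
# fold execution
# ---------------------------------------------------------------------------

def _fold_pairs(plan: CVPlan, dataset: Dataset, rep: int, fold: int):
    """(train_pairs, test_pairs) as (k, 2) index arrays for one fold."""
    n_d, n_t = dataset.n_drugs, dataset.n_targets
    test_units = plan.assignments[rep][fold]
    all_units = np.concatenate(plan.assignments[rep])
    train_units = np.setdiff1d(all_units, test_units)
    if plan.setting == "CVS1":
        to_pairs = lambda flat: np.column_stack([flat // n_t, flat % n_t])
        return to_pairs(train_units), to_pairs(test_units)
    if plan.setting == "CVS2":
        grid = lambda drugs: np.array(
            [(i, j) for i in drugs for j in range(n_t)], dtype=int
        ).reshape(-1, 2)
        return grid(train_units), grid(test_units)
    grid = lambda targets: np.array(
        [(i, j) for i in range(n_d) for j in targets], dtype=int
    ).reshape(-1, 2)
    return grid(train_units), grid(test_units)


def audit_plan(plan: CVPlan, dataset: Dataset) -> int:
    """Count blinding violations: test entities appearing in any training pair."""
    violations = 0
    axis = {"CVS1": None, "CVS2": 0, "CVS3": 1}[plan.setting]
    for r in range(plan.n_repeats):
        for f in range(plan.n_folds):
            train_pairs, test_pairs = _fold_pairs(plan, dataset, r, f)
            if axis is None:
                both = set(map(tuple, train_pairs)) & set(map(tuple, test_pairs))
                violations += len(both)
            else:
                overlap = set(train_pairs[:, axis]) & set(test_pairs[:, axis])
                violations += len(overlap)
    return violations


def run_cv(
    dataset: Dataset,
    plan: CVPlan,
    model_configs: ModelConfigs,
    smote_cfg: SmoteConfig | None = None,
    features: tuple[np.ndarray, np.ndarray] | None = None,
    shuffle_labels_seed: int | None = None,
) -> CVResult:
    """Full cross-validated evaluation of the pipeline under one plan.

    `features` may carry precomputed (H_d, H_t) to reuse across settings
    (the extractor is unsupervised, so this cannot leak labels).
    `shuffle_labels_seed`, if given, permutes Y's entries before training
    and scoring - the label-shuffled null experiment.
    """
    if features is None:
        H_d, H_t = extract_features(
            dataset,
            model_configs.drug_layers,
            model_configs.target_layers,
            model_configs.rwr,
            model_configs.mda_train,
        )
    else:
        H_d, H_t = features
    Y = dataset.interactions.y
    if shuffle_labels_seed is not None:
        rng = np.random.default_rng(shuffle_labels_seed)
        Y = rng.permutation(Y.ravel()).reshape(Y.shape)

    per_repeat_auc, per_repeat_aupr = [], []
    fold_records, skipped = [], []
    for r in range(plan.n_repeats):
        pooled_scores, pooled_labels = [], []
        for f in range(plan.n_folds):
            train_pairs, test_pairs = _fold_pairs(plan, dataset, r, f)
            train_ds = make_pairs(H_d, H_t, Y, train_pairs)
            if smote_cfg is not None:
                fold_smote = SmoteConfig(
                    k_neighbors=smote_cfg.k_neighbors,
                    target_ratio=smote_cfg.target_ratio,
                    seed=derive_seed(smote_cfg.seed, f"smote-r{r}f{f}"),
                )
                train_ds = smote(train_ds, fold_smote)
            dnn_cfg = model_configs.dnn
            fold_cfg = DNNConfig(
                hidden_widths=dnn_cfg.hidden_widths,
                dropout_p=dnn_cfg.dropout_p,
                momentum=dnn_cfg.momentum,
                learning_rate=dnn_cfg.learning_rate,
                max_epochs=dnn_cfg.max_epochs,
                patience=dnn_cfg.patience,
                val_fraction=dnn_cfg.val_fraction,
                batch_size=dnn_cfg.batch_size,
                seed=derive_seed(dnn_cfg.seed, f"dnn-r{r}f{f}"),
            )
            model = train_dnn(train_ds, fold_cfg)
            test_ds = make_pairs(H_d, H_t, Y, test_pairs)
            scores = predict_proba(model, test_ds.features)
            pooled_scores.append(scores)
            pooled_labels.append(test_ds.labels)
            rec = {"repeat": r, "fold": f, "n_test": len(scores)}
            if len(np.unique(test_ds.labels)) == 2:
                rec["auc"] = auc(test_ds.labels, scores)
                rec["aupr"] = aupr(test_ds.labels, scores)
            else:
                skipped.append((r, f, "single-class test fold"))
                logger.warning("repeat %d fold %d: single-class test fold, metric skipped", r, f)
            fold_records.append(rec)
        ys = np.concatenate(pooled_labels)
        ss = np.concatenate(pooled_scores)
        per_repeat_auc.append(auc(ys, ss))
        per_repeat_aupr.append(aupr(ys, ss))
    return CVResult(
        setting=plan.setting,
        per_repeat_auc=per_repeat_auc,
        per_repeat_aupr=per_repeat_aupr,
        fold_records=fold_records,
        skipped_folds=skipped,
    )


def paired_t_bootstrap(a, b, n_boot: int = 2000, seed: int = 0) -> float:
    """Two-sided bootstrap paired t-test p-value for mean(a) != mean(b).

    The observed paired t statistic is compared against a null distribution
    built from `n_boot` resamples of the mean-centred paired differences.
    All-identical inputs give p = 1.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.all(d == 0):
        return 1.0
    n = len(d)

    def t_stat(x):
        s = x.std(ddof=1)
        if s == 0:
            return 0.0 if x.mean() == 0 else np.inf * np.sign(x.mean())
        return x.mean() / (s / np.sqrt(n))

    t_obs = t_stat(d)
    centred = d - d.mean()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_boot):
        t_b = t_stat(centred[rng.integers(0, n, size=n)])
        if abs(t_b) >= abs(t_obs):
            hits += 1
    return (1 + hits) / (n_boot + 1)
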