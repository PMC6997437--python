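"""Pair-feature construction and the deep neural network that scores
drug-target pairs.

A pair (i, j) is represented by concatenating drug i's and target j's fused
feature rows.  The classifier is a fully-connected net, by default
input -> 300 -> 200 -> 100 -> 1, ReLU hidden units with dropout p = 0.5
during training, a single sigmoid output unit, trained with momentum SGD on
the binary cross-entropy.  Early stopping monitors accuracy on an internal
stratified validation split and restores the best-epoch weights when
accuracy has not risen for `patience` consecutive epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from ._nn import bce, derive_seed, init_dense, relu, sgd_momentum_step, sigmoid


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class PairDataset:
    """Labelled (or unlabelled, for prediction) drug-target pair rows.

    pairs[k] = (drug index, target index); synthetic oversampled rows use
    (-1, -1).  features[k] = [H_d[i] || H_t[j]].
    """

    pairs: np.ndarray  # (n, 2) int
    features: np.ndarray  # (n, d)
    labels: np.ndarray | None = None  # (n,) in {0,1}

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] != len(self.pairs):
            raise ValueError("features row count must equal pair count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8).ravel()
            if len(self.labels) != len(self.pairs):
                raise ValueError("labels length must equal pair count")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]


def make_pairs(
    H_d: np.ndarray,
    H_t: np.ndarray,
    Y: np.ndarray | None,
    pair_index_list,
) -> PairDataset:
    """Assemble pair features (and labels from Y if given) in list order."""
    pairs = np.asarray(list(pair_index_list), dtype=int).reshape(-1, 2)
    if len(pairs) == 0:
        d = H_d.shape[1] + H_t.shape[1]
        return PairDataset(
            pairs=np.empty((0, 2), dtype=int),
            features=np.empty((0, d)),
            labels=None if Y is None else np.empty(0, dtype=np.int8),
        )
    if pairs[:, 0].min() < 0 or pairs[:, 0].max() >= H_d.shape[0]:
        raise IndexError("drug index out of range")
    if pairs[:, 1].min() < 0 or pairs[:, 1].max() >= H_t.shape[0]:
        raise IndexError("target index out of range")
    feats = np.concatenate([H_d[pairs[:, 0]], H_t[pairs[:, 1]]], axis=1)
    labels = None if Y is None else np.asarray(Y)[pairs[:, 0], pairs[:, 1]]
    return PairDataset(pairs=pairs, features=feats, labels=labels)


@dataclass(frozen=True)
class DNNConfig:
    hidden_widths: tuple[int, ...] = (300, 200, 100)
    dropout_p: float = 0.5
    momentum: float = 0.9
    learning_rate: float = 0.01
    max_epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.1
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0,1)")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in [0,1)")
        if self.max_epochs < 1 or self.patience < 1 or self.batch_size < 1:
            raise ValueError("max_epochs, patience, batch_size must be >= 1")


class DNNModel:
    """Fully-connected classifier with per-layer trainable flags.

    Layers are (W, b) pairs: hidden layers then the single-unit output
    layer.  `trainable[k]` gates updates to layer k (used by the transfer-
    learning freeze).
    """

    def __init__(self, input_dim: int, config: DNNConfig, seed: int | None = None):
        self.config = config
        self.input_dim = int(input_dim)
        seed = config.seed if seed is None else seed
        rng = np.random.default_rng(derive_seed(seed, "dnn-init"))
        dims = [self.input_dim, *config.hidden_widths, 1]
        self.layers = [
            init_dense(rng, dims[k], dims[k + 1], gain=(np.sqrt(2.0) if k < len(dims) - 2 else 1.0))
            for k in range(len(dims) - 1)
        ]
        self.trainable = [True] * len(self.layers)
        self.history: dict[str, list[float]] = {}

    # -- plumbing -----------------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [arr for W, b in self.layers for arr in (W, b)]

    def trainable_parameter_count(self) -> int:
        return sum(W.size + b.size for (W, b), t in zip(self.layers, self.trainable) if t)

    def copy_weights(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(W.copy(), b.copy()) for W, b in self.layers]

    def set_weights(self, weights) -> None:
        self.layers = [(W.copy(), b.copy()) for W, b in weights]

    def reinit_output_layer(self, seed: int) -> None:
        rng = np.random.default_rng(derive_seed(seed, "dnn-out-reinit"))
        fan_in = self.layers[-1][0].shape[0]
        self.layers[-1] = init_dense(rng, fan_in, 1)

    # -- forward ------------------------------------------------------------
    def _forward(self, x: np.ndarray, dropout_rng: np.random.Generator | None):
        """Returns (probabilities, cache).  Dropout only when a rng is given
        (training mode); inference is deterministic."""
        p = self.config.dropout_p
        acts = [x]
        masks = []
        a = x
        for W, b in self.layers[:-1]:
            a = relu(a @ W + b)
            if dropout_rng is not None and p > 0:
                mask = (dropout_rng.random(a.shape) >= p) / (1.0 - p)
                a = a * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(a)
        Wo, bo = self.layers[-1]
        prob = sigmoid(a @ Wo + bo).ravel()
        return prob, (acts, masks)

    def _backward(self, y: np.ndarray, prob: np.ndarray, cache):
        acts, masks = cache
        B = len(y)
        delta = ((prob - y) / B)[:, None]  # sigmoid+BCE at output
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.layers)
        for k in range(len(self.layers) - 1, -1, -1):
            W, _ = self.layers[k]
            a_in = acts[k]
            grads[k] = (a_in.T @ delta, delta.sum(axis=0))
            if k > 0:
                delta = delta @ W.T
                if masks[k - 1] is not None:
                    delta = delta * masks[k - 1]
                delta = delta * (acts[k] > 0)  # ReLU derivative through the kept units
        return grads


def train_dnn(train: PairDataset, cfg: DNNConfig, model: DNNModel | None = None) -> DNNModel:
    """Train the pair classifier with momentum SGD, dropout, early stopping.

    Deterministic for a fixed config seed.  Raises on single-class input or
    non-finite loss.  When an existing `model` is passed (transfer-learning
    finetune), training continues in place and its per-layer trainable flags
    are honoured; otherwise a fresh model is initialised from the config seed.
    """
    if train.labels is None:
        raise ValueError("training requires labels")
    y_all = train.labels.astype(float)
    if len(np.unique(y_all)) < 2:
        raise ValueError("training data must contain both classes")
    X_all = train.features

    if model is None:
        model = DNNModel(train.feature_dim, cfg)
    elif model.input_dim != train.feature_dim:
        raise ValueError("existing model input dim does not match training features")
    if cfg.val_fraction > 0:
        try:
            X_tr, X_val, y_tr, y_val = train_test_split(
                X_all,
                y_all,
                test_size=cfg.val_fraction,
                stratify=y_all,
                random_state=derive_seed(cfg.seed, "dnn-valsplit") % (2**32),
            )
        except ValueError:  # too few minority rows to stratify
            X_tr, X_val, y_tr, y_val = train_test_split(
                X_all,
                y_all,
                test_size=cfg.val_fraction,
                random_state=derive_seed(cfg.seed, "dnn-valsplit") % (2**32),
            )
    else:
        X_tr, y_tr, X_val, y_val = X_all, y_all, None, None

    params = model.parameters()
    vels = [np.zeros_like(p) for p in params]
    shuffle_rng = np.random.default_rng(derive_seed(cfg.seed, "dnn-shuffle"))
    drop_rng = np.random.default_rng(derive_seed(cfg.seed, "dnn-dropout"))
    n = len(X_tr)
    best_acc, best_weights, best_epoch, stale = -np.inf, model.copy_weights(), 0, 0
    hist_loss, hist_tracc, hist_vacc = [], [], []
    for epoch in range(cfg.max_epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X_tr[idx], y_tr[idx]
            prob, cache = model._forward(xb, drop_rng)
            loss = bce(yb, prob)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch + 1}")
            grads = model._backward(yb, prob, cache)
            flat_p, flat_g, flat_v = [], [], []
            for k, (gW, gb) in enumerate(grads):
                if model.trainable[k]:
                    W, b = model.layers[k]
                    flat_p += [W, b]
                    flat_g += [gW, gb]
                    flat_v += [vels[2 * k], vels[2 * k + 1]]
            sgd_momentum_step(flat_p, flat_g, flat_v, cfg.learning_rate, cfg.momentum)
            epoch_loss += loss
            n_batches += 1
        hist_loss.append(epoch_loss / n_batches)
        tr_prob, _ = model._forward(X_tr, None)
        hist_tracc.append(float(np.mean((tr_prob > 0.5) == (y_tr > 0.5))))
        if X_val is not None and len(X_val):
            val_prob, _ = model._forward(X_val, None)
            val_acc = float(np.mean((val_prob > 0.5) == (y_val > 0.5)))
            hist_vacc.append(val_acc)
            if val_acc > best_acc:
                best_acc, best_weights, best_epoch, stale = val_acc, model.copy_weights(), epoch, 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if X_val is not None and len(X_val):
        model.set_weights(best_weights)
    model.history = {
        "loss": hist_loss,
        "train_accuracy": hist_tracc,
        "val_accuracy": hist_vacc,
        "best_epoch": [best_epoch],
    }
    return model


def predict_proba(model: DNNModel, features: np.ndarray) -> np.ndarray:
    """Interaction probabilities with dropout disabled; deterministic."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != model.input_dim:
        raise ValueError(
            f"feature dim {features.shape} does not match model input {model.input_dim}"
        )
    prob, _ = model._forward(features, None)
    return prob


def classify(probabilities: np.ndarray) -> np.ndarray:
    """Binary decision: interaction iff probability strictly exceeds 0.5."""
    p = np.asarray(probabilities, dtype=float)
    return (p > 0.5).astype(np.int8)
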