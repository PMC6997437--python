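"""Multimodal deep autoencoder (MDA) fusing per-modality topological
similarity matrices into low-dimensional entity features.

The samples are entity ROWS: drug i's input under modality j is row i of
that modality's m x m topological matrix, so the fused feature matrix has
one row per entity.  Architecture, for n modalities with per-modality branch
widths [w1, ..., wk] and bottleneck d:

    encoder   x_j (m) -> w1 -> ... -> wk        (one branch per modality)
    fusion    concat(n * wk) -> d               (shared feature layer, H_c)
    decoder   d -> wk -> ... -> w1 -> m         (one mirrored branch per modality)

All activations are sigmoid.  Training minimises the sum over modalities of
the element-averaged binary cross-entropy between each input matrix and its
reconstruction, by minibatch SGD over entity rows.  The model never sees
interaction labels: feature extraction is fully unsupervised.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._nn import bce, derive_seed, init_dense, sgd_momentum_step, sigmoid
from .dataset_model import Dataset
from .toposim import RWRConfig, TopoFeatureSet, topologize


class ConfigError(ValueError):
    pass


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class LayerConfig:
    """Architecture of one MDA.

    branch_widths are the per-modality encoder widths (the "n*k" entries of
    a layer-configuration string); bottleneck is the shared feature-layer
    width (the bare integer).  The decoder mirrors the encoder.
    """

    n_modalities: int
    input_dim: int
    branch_widths: tuple[int, ...] = ()
    bottleneck: int = 50

    def __post_init__(self) -> None:
        if self.n_modalities < 1 or self.input_dim < 1:
            raise ConfigError("n_modalities and input_dim must be >= 1")
        if self.bottleneck < 1:
            raise ConfigError(f"bottleneck must be >= 1, got {self.bottleneck}")
        if any(int(w) != w or w < 1 for w in self.branch_widths):
            raise ConfigError(f"branch widths must be positive integers: {self.branch_widths}")

    @staticmethod
    def parse_widths(text: str) -> tuple[tuple[int, ...], int]:
        """Parse a layer-configuration string into (branch_widths, bottleneck).

        Accepts the full symmetric form "[n*m, n*100, n*75, 50, n*75, n*100, n*m]"
        (symbolic n*m / n*n_d / n*n_t endpoints are skipped, the decoder half
        must mirror the encoder half) or the encoder-only shorthand "n*100,50".
        """
        tokens = [t.strip() for t in text.strip().strip("[]").split(",") if t.strip()]
        branch: list[int] = []
        bottleneck = None
        tail: list[int] = []
        for tok in tokens:
            m = re.fullmatch(r"n\s*\*\s*(\w+)", tok)
            if m:
                if m.group(1).isdigit():
                    (branch if bottleneck is None else tail).append(int(m.group(1)))
                # symbolic n*m / n*n_d / n*n_t endpoint: skip
            elif tok.isdigit():
                if bottleneck is not None:
                    raise ConfigError(f"two bottleneck entries in {text!r}")
                bottleneck = int(tok)
            else:
                raise ConfigError(f"cannot parse layer token {tok!r} in {text!r}")
        if bottleneck is None:
            raise ConfigError(f"no bottleneck width in {text!r}")
        if tail and tail != branch[::-1]:
            raise ConfigError(f"decoder half {tail} does not mirror encoder half {branch}")
        return tuple(branch), bottleneck

    @classmethod
    def from_string(cls, text: str, n_modalities: int, input_dim: int) -> "LayerConfig":
        branch, bottleneck = cls.parse_widths(text)
        return cls(n_modalities, input_dim, branch, bottleneck)


@dataclass(frozen=True)
class MDATrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 0.001
    momentum: float = 0.9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate < 0:
            raise ConfigError("epochs, batch_size must be >=1 and learning_rate >= 0")


class MDAModel:
    """Parameter container with explicit forward/backward passes."""

    def __init__(self, config: LayerConfig, seed: int):
        self.config = config
        self.rng_seed = int(seed)
        rng = np.random.default_rng(self.rng_seed)
        n, m, d = config.n_modalities, config.input_dim, config.bottleneck
        widths = list(config.branch_widths)
        # per-modality encoder branches: m -> w1 -> ... -> wk
        self.enc: list[list[tuple[np.ndarray, np.ndarray]]] = []
        for _ in range(n):
            layers, prev = [], m
            for w in widths:
                layers.append(init_dense(rng, prev, w, gain=4.0))
                prev = w
            self.enc.append(layers)
        concat_dim = n * (widths[-1] if widths else m)
        # shared fusion layer -> bottleneck
        self.fusion = init_dense(rng, concat_dim, d, gain=4.0)
        # per-modality decoder branches: d -> wk -> ... -> w1 -> m
        self.dec: list[list[tuple[np.ndarray, np.ndarray]]] = []
        dec_widths = widths[::-1] + [m]
        for _ in range(n):
            layers, prev = [], d
            for w in dec_widths:
                layers.append(init_dense(rng, prev, w, gain=4.0))
                prev = w
            self.dec.append(layers)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        flat = []
        for branch in self.enc:
            for W, b in branch:
                flat += [W, b]
        flat += [self.fusion[0], self.fusion[1]]
        for branch in self.dec:
            for W, b in branch:
                flat += [W, b]
        return flat

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward / backward -------------------------------------------------
    def _forward(self, xs: list[np.ndarray]):
        """Full pass; returns (reconstructions, cache) for backprop."""
        enc_acts = []  # per modality: list of activations incl. input
        for j, branch in enumerate(self.enc):
            acts = [xs[j]]
            for W, b in branch:
                acts.append(sigmoid(acts[-1] @ W + b))
            enc_acts.append(acts)
        H = np.concatenate([acts[-1] for acts in enc_acts], axis=1)
        Wc, bc = self.fusion
        Hc = sigmoid(H @ Wc + bc)
        dec_acts = []
        for branch in self.dec:
            acts = [Hc]
            for W, b in branch:
                acts.append(sigmoid(acts[-1] @ W + b))
            dec_acts.append(acts)
        recon = [acts[-1] for acts in dec_acts]
        return recon, (enc_acts, H, Hc, dec_acts)

    def _backward(self, xs: list[np.ndarray], cache) -> list[np.ndarray]:
        """Gradients of the modality-summed, element-averaged BCE loss,
        in the order of :meth:`parameters`."""
        enc_acts, H, Hc, dec_acts = cache
        n = self.config.n_modalities
        B = xs[0].shape[0]
        grads_enc = [[None] * len(br) for br in self.enc]
        grads_dec = [[None] * len(br) for br in self.dec]
        dHc = np.zeros_like(Hc)
        for j in range(n):
            acts = dec_acts[j]
            # sigmoid + BCE at the output head: dL/dz = (xhat - x)/(B*m)
            delta = (acts[-1] - xs[j]) / (B * xs[j].shape[1])
            for li in range(len(self.dec[j]) - 1, -1, -1):
                W, _ = self.dec[j][li]
                a_in = acts[li]
                grads_dec[j][li] = (a_in.T @ delta, delta.sum(axis=0))
                delta_in = delta @ W.T
                if li == 0:
                    dHc += delta_in
                else:
                    delta = delta_in * a_in * (1.0 - a_in)
        Wc, _ = self.fusion
        delta_c = dHc * Hc * (1.0 - Hc)
        grad_fusion = (H.T @ delta_c, delta_c.sum(axis=0))
        dH = delta_c @ Wc.T
        width = H.shape[1] // n
        for j in range(n):
            delta_up = dH[:, j * width : (j + 1) * width]
            acts = enc_acts[j]
            delta = delta_up * acts[-1] * (1.0 - acts[-1]) if self.enc[j] else None
            for li in range(len(self.enc[j]) - 1, -1, -1):
                W, _ = self.enc[j][li]
                a_in = acts[li]
                grads_enc[j][li] = (a_in.T @ delta, delta.sum(axis=0))
                if li > 0:
                    delta = (delta @ W.T) * a_in * (1.0 - a_in)
        flat: list[np.ndarray] = []
        for branch in grads_enc:
            for gW, gb in branch:
                flat += [gW, gb]
        flat += [grad_fusion[0], grad_fusion[1]]
        for branch in grads_dec:
            for gW, gb in branch:
                flat += [gW, gb]
        return flat

    def loss(self, xs: list[np.ndarray]) -> float:
        recon, _ = self._forward(xs)
        return float(sum(bce(x, r) for x, r in zip(xs, recon)))


def build_mda(config: LayerConfig, seed: int) -> MDAModel:
    """Deterministically initialised MDA for the given architecture."""
    return MDAModel(config, seed)


def _check_topo(model: MDAModel, topo: TopoFeatureSet) -> list[np.ndarray]:
    cfg = model.config
    if topo.n_views != cfg.n_modalities:
        raise ValueError(f"model expects {cfg.n_modalities} modalities, got {topo.n_views}")
    if len(topo.labels) != cfg.input_dim:
        raise ValueError(f"model expects {cfg.input_dim} entities, got {len(topo.labels)}")
    return [np.asarray(X, dtype=float) for X in topo.matrices]


def encode(model: MDAModel, topo: TopoFeatureSet) -> np.ndarray:
    """Bottleneck activations, one row per entity; entries in (0,1)."""
    xs = _check_topo(model, topo)
    _, (_, _, Hc, _) = model._forward(xs)
    return Hc


def decode(model: MDAModel, Hc: np.ndarray) -> list[np.ndarray]:
    """Per-modality reconstructions of shape (m, m) from bottleneck rows."""
    Hc = np.asarray(Hc, dtype=float)
    if Hc.ndim != 2 or Hc.shape[1] != model.config.bottleneck:
        raise ValueError(f"H_c must have {model.config.bottleneck} columns, got {Hc.shape}")
    out = []
    for branch in model.dec:
        a = Hc
        for W, b in branch:
            a = sigmoid(a @ W + b)
        out.append(a)
    return out


def train_mda(
    model: MDAModel, topo: TopoFeatureSet, train_cfg: MDATrainConfig
) -> tuple[MDAModel, list[float]]:
    """Minibatch-SGD training of the reconstruction loss over entity rows.

    Returns the model (trained in place) and the full-data loss recorded at
    the end of every epoch.  Deterministic for a fixed seed.
    """
    xs = _check_topo(model, topo)
    m = xs[0].shape[0]
    params = model.parameters()
    vels = [np.zeros_like(p) for p in params]
    shuffle_rng = np.random.default_rng(derive_seed(train_cfg.rng_seed, "mda-shuffle"))
    trace: list[float] = []
    for epoch in range(train_cfg.epochs):
        order = shuffle_rng.permutation(m)
        for start in range(0, m, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            batch = [x[idx] for x in xs]
            recon, cache = model._forward(batch)
            grads = model._backward(batch, cache)
            sgd_momentum_step(params, grads, vels, train_cfg.learning_rate, train_cfg.momentum)
        epoch_loss = model.loss(xs)
        if not np.isfinite(epoch_loss):
            raise TrainingDivergedError(f"non-finite loss at epoch {epoch + 1}")
        trace.append(epoch_loss)
    return model, trace


def extract_features(
    dataset: Dataset,
    drug_cfg: LayerConfig,
    target_cfg: LayerConfig,
    rwr_cfg: RWRConfig,
    train_cfg: MDATrainConfig,
    scale: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Unsupervised drug and target feature matrices (n_d x d_d, n_t x d_t).

    Runs RWR+PPMI per modality, then trains two independent MDAs.  The
    interaction matrix Y is never read.
    """
    out = []
    for sims, cfg, stage in (
        (dataset.drug_sims, drug_cfg, "mda-drug"),
        (dataset.target_sims, target_cfg, "mda-target"),
    ):
        topo = topologize(sims, rwr_cfg, scale=scale)
        model = build_mda(cfg, derive_seed(train_cfg.rng_seed, stage))
        sub_cfg = MDATrainConfig(
            epochs=train_cfg.epochs,
            batch_size=train_cfg.batch_size,
            learning_rate=train_cfg.learning_rate,
            momentum=train_cfg.momentum,
            rng_seed=derive_seed(train_cfg.rng_seed, stage),
        )
        model, _ = train_mda(model, topo, sub_cfg)
        out.append(encode(model, topo))
    return out[0], out[1]
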