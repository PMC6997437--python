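# mdadti

Drug–target interaction (DTI) prediction from multiple similarity networks.

Knowing which proteins a compound binds is central to drug discovery and
repositioning, but experimental screening covers only a sliver of the
compound × protein space. A long-standing computational shortcut is *guilt
by association*: similar drugs tend to interact with similar targets. In
practice one has several heterogeneous similarity measures per entity —
chemical-structure and side-effect similarity between drugs; sequence, GO
and PPI-proximity similarity between proteins — each a square matrix in
[0, 1], plus a sparse binary interaction matrix **Y**.

`mdadti` implements a similarity-network-fusion pipeline for this setting:

1. **Topological featurization.** Each similarity matrix S⁽ʲ⁾ is treated as
   a weighted graph. A random walk with restart (RWR) is run from every
   node on the row-normalised transition matrix Ŝ,

       pᵢ(t) = α · pᵢ(t−1) Ŝ + (1 − α) · pᵢ(0),    pᵢ = Σ_{t=1..T} pᵢ(t),

   and positive pointwise mutual information (PPMI) converts the
   accumulated walk matrix P into a topological similarity matrix

       X_ik = max(0, log₂( P_ik · ΣP / (Σ_k P_ik · Σ_i P_ik) )),

   which encodes each node's position in the *global* network structure,
   not just its pairwise similarities.
2. **Multimodal autoencoder fusion (MDA).** The per-modality matrices are
   fused by an autoencoder with one encoder/decoder branch per modality
   joined at a shared sigmoid bottleneck; its activations are the
   low-dimensional entity features H꜀. Training minimises the summed
   per-modality cross-entropy reconstruction error and never touches **Y**.
3. **DNN classification.** A pair (drug i, target j) is represented by
   concatenating the two feature rows and scored by a fully-connected
   network (300/200/100 ReLU hidden units, dropout, sigmoid output) trained
   with momentum SGD, SMOTE oversampling of the rare positives, and
   accuracy-based early stopping; probability > 0.5 ⇒ predicted interaction.

Evaluation follows the field's blinded protocol: repeated 10-fold
cross-validation holding out random **pairs** (CVS1), whole **drugs**
(CVS2) or whole **targets** (CVS3), scored by AUC and AUPR, with a
bootstrap paired t-test for method comparison, a transfer-learning mode for
small datasets (freeze everything but the output layer), and ranking of
unknown pairs by predicted probability.

The package consumes precomputed similarity matrices as delimited text; it
does not compute chemical or sequence kernels itself. A seeded synthetic
generator (`mdadti.synthetic`) produces desk-scale datasets with the
structure the method assumes — several noisy similarity views of a planted
cluster structure and interactions concentrated between matched clusters —
so the whole pipeline is testable without external downloads.

## Worked example

```python
import numpy as np
from mdadti import (
    SynthConfig, generate, ModelConfigs, RWRConfig, LayerConfig,
    MDATrainConfig, DNNConfig, SmoteConfig, make_cv_plan, run_cv,
)

dataset, clusters = generate(SynthConfig(seed=1))   # 60 drugs x 40 targets
configs = ModelConfigs(
    rwr=RWRConfig(),                                # alpha=0.9, T=10
    drug_layers=LayerConfig(3, 60, (), 50),         # 3 views -> 50-dim features
    target_layers=LayerConfig(3, 40, (), 25),
    mda_train=MDATrainConfig(rng_seed=11),
    dnn=DNNConfig(seed=12, dropout_p=0.2),
)
plan = make_cv_plan(dataset, "CVS1", seed=13, n_folds=10, n_repeats=1)
res = run_cv(dataset, plan, configs, SmoteConfig(seed=14))
print(f"AUC {res.mean_auc:.3f}  AUPR {res.mean_aupr:.3f}  "
      f"prevalence {dataset.interactions.y.mean():.3f}")
```

prints

```
AUC 0.877  AUPR 0.591  prevalence 0.222
```

i.e. under pair-blinded 10-fold cross-validation the pipeline ranks unknown
pairs essentially as well as the generator's own Bayes-optimal scorer (true
cluster-cell interaction rates give AUC 0.877 on this dataset), against a
positive rate of 22%. Shuffling the labels (`shuffle_labels_seed=` in
`run_cv`) collapses the AUC to ≈ 0.5.

There is also a CLI:

```bash
mdadti synth --out data/                      # write a synthetic dataset as TSVs
mdadti toposim --manifest data/manifest.yaml --out topo/
mdadti run --config pipeline.yaml --out results/
```

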