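# pathofuse

Multi-scale transformer and multimodal variational-auto-encoder toolkit
for prescreening **germline BRCA1/2 mutation carriers** from breast-cancer
whole-slide images (WSIs) and electronic-health-record phenotypes — built
as a desk-scale, fully synthetic-testable library with scikit-learn-style
estimators.

Identifying germline BRCA1/2 carriers guides PARP-inhibitor therapy and
cascade genetic testing, but sequencing every patient is costly and
clinical criteria miss many carriers.  Carrier tumors leave morphological
traces — immune infiltration, stromal changes, nuclear heterogeneity —
that a slide-level model can read, and clinical phenotypes (receptor
status, family history, age) carry complementary signal.  `pathofuse`
implements the full computational pipeline for this problem:

* **WSI pre-processing** (`pathofuse.patches`): tessellation into
  224/512-px patches, tissue filtering (< 50 % tissue dropped), tumor
  patch labelling (> 25 % tumor area), pluggable patch encoders, and
  clustering-based bag sampling (k-means with `N_c` clusters, `N_s`
  uniform draws per cluster, 30 × 60 per scale by default).
* **Slide model** (`pathofuse.transformer`): a two-branch transformer
  over the sampled tokens Z_l, Z_h — per-branch embedding
  (linear → batch-norm → ReLU), learnable class tokens, and 12 blocks
  alternating within-branch self-attention with cross-scale attention

      Attention(Q, K, V) = softmax(Q Kᵀ / √d_k) V,
      Q = X W_Q, K = X W_K, V = X W_V  (12 heads, d_k = 64)

  where in cross-attention each branch's tokens query the other
  branch's keys/values.  The two class tokens concatenate into a
  **1536-d slide feature** feeding a single-logit head.  Patient scores
  average slide scores.
* **Attribution** (`pathofuse.attribution`): integrated gradients
  IG_i = (x_i − x'_i) ∫₀¹ ∂F/∂x_i (x' + α(x − x')) dα on the logit,
  repeated-sampling slide maps, and representative-patch selection.
* **Microenvironment** (`pathofuse.microenv`): 14 per-nucleus
  morphology/texture descriptors, per-type densities, 8-adjacency
  cell-cell contacts, the 15 distinct-type interaction abundances
  (contacts ÷ total cells per patch), and rank-test / odds-ratio group
  statistics.
* **Multimodal fusion** (`pathofuse.fusion`): a two-channel VAE with the
  objective L = β·(KL_patho + KL_pheno) − Σ_{i,j} log p(X_i | Z_j)
  (self- and cross-reconstruction, reparameterised latents
  Z = μ + ε·σ), a fused classification head on the concatenated
  posterior means, and permutation-sampling Shapley contributions.
* **Evaluation** (`pathofuse.evaluation`): bootstrap AUC CIs,
  sensitivity/specificity operating points, percentile enrichment, odds
  ratios, and the slides-per-patient subsampling experiment.
* **Synthetic data** (`pathofuse.simulate`): seeded generators for every
  input above — planted-signal embedding cohorts, phenotype tables with
  exact log-odds calibration, toy slides, and typed nuclei masks with
  ground-truth contact lists — so the whole pipeline is testable without
  any clinical data.

All neural components run on a small reverse-mode autodiff core
(`pathofuse.nn`) over numpy, verified against central differences.

## Worked example

```python
import numpy as np
from sklearn.metrics import roc_auc_score
from pathofuse import simulate as sim
from pathofuse.patches import SamplerConfig, cluster_sample
from pathofuse.transformer import (CrossScaleTransformerClassifier,
                                   ModelConfig, TrainConfig)

# 120 patients, carrier fraction 0.3; carrier slides' patch embeddings
# are shifted by 2 noise-SD along a hidden direction.
spec = sim.SyntheticCohortSpec(n_patients=120, slides_per_patient=(1.0,),
                               embed_dim=16, patch_counts={224: 24, 512: 24},
                               signal_strength=2.0, seed=1)
cohort = sim.gen_embedding_cohort(spec)

pairs = []
for s in cohort.slides:                       # 3 clusters x 4 draws / scale
    tok_l, _ = cluster_sample(s.bags[224], SamplerConfig(3, 4, seed=1))
    tok_h, _ = cluster_sample(s.bags[512], SamplerConfig(3, 4, seed=2))
    pairs.append((tok_l, tok_h))
y = cohort.slide_labels

clf = CrossScaleTransformerClassifier(
    ModelConfig(d=32, d_k=8, n_heads=2, n_blocks=2, c_l=3, s_l=4,
                c_h=3, s_h=4, d_in_low=16, d_in_high=16),
    TrainConfig(lr=1e-3, batch_size=32, max_epochs=30, patience=10,
                warmup_epochs=3, cosine_t_max=27, n_folds=4))
clf.fit(pairs[:90], y[:90], groups=[s.patient_id for s in cohort.slides[:90]])

print("fold validation AUCs:", clf.fold_aucs_)
print("held-out slide AUC:  ",
      roc_auc_score(y[90:], clf.decision_function(pairs[90:])))
```

Output:

```
fold validation AUCs: [1. 1. 1. 1.]
held-out slide AUC:   1.0
```

Each fold's best-epoch validation AUC reaches 1.0 on this planted-signal
cohort, and the selected model separates the 30 held-out slides
perfectly — the transformer recovers a 2-SD bag-level mean shift, as the
logistic-regression oracle on bag means says it should.  With
`signal_strength=0` the same pipeline stays at chance.

A command-line interface mirrors the library
(`pathofuse simulate | tessellate | sample | train-wise | run |
microenv | evaluate`, all with `--seed`).

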