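# Methods

`pathofuse` implements a desk-scale, fully synthetic-testable version of a
multimodal pipeline for prescreening germline BRCA1/2 mutation carriers
from breast-cancer histopathology and clinical phenotypes.  This note
describes the models, the choices that were genuinely open, the synthetic
data the tests run on, and what passing those tests does and does not
establish.

## Problem setting

Whole-slide images (WSIs) are gigapixel scans; supervision exists only at
the slide or patient level (carrier / non-carrier of a pathogenic germline
BRCA1/2 variant).  The pipeline therefore treats a slide as a *bag* of
patch embeddings at two physical scales (224 px and 512 px at 20x), pools
the bag with a learned two-branch transformer into a single slide
representation and logit, and optionally fuses that representation with
standardized electronic-health-record phenotypes through a multi-channel
variational auto-encoder (mcVAE) and a small classification head.
Interpretability comes from integrated-gradients attribution over patch
tokens, and biological characterisation from nucleus morphometry and
spatial cell-cell interaction statistics computed on segmenter output.

## Slide model

**Input construction.** Slides are tessellated into non-overlapping
patches; patches under 50% tissue (HSV saturation > 0.05 and gray
luminance < 0.9 defines tissue pixels; the boundary fraction 0.5 is kept)
are dropped; optionally only tumor patches (strictly more than 25% tumor
area) are retained.  Patch embeddings (768-d by default, encoder
pluggable) are k-means-clustered (k-means++ init, 10 restarts, tol 1e-4,
seeded) into `n_clusters` groups and `n_samples` patches are drawn
uniformly per cluster — 30 x 60 per scale by default — with replacement
inside clusters smaller than `n_samples`, so the model input always has a
fixed shape.  Stratifying the sample by cluster protects rare
morphologies that uniform sampling would miss.

**Architecture.** Each branch embeds its tokens (linear -> batch
standardisation -> ReLU), prepends a learnable class token, and runs
through 12 pre-norm residual blocks (4x GELU feed-forward, no positional
encoding: cluster-sampled tokens carry no order, and the slide logit is
permutation-invariant by construction).  Even-indexed blocks self-attend
within each branch; odd-indexed blocks cross-attend — each branch's full
token set (class token included) queries the other branch's tokens as
keys/values, with per-head projections of width 64 and 12 heads.  The two
final class tokens concatenate into a 1536-d slide feature feeding a
linear head with a single logit.

One implementation detail is load-bearing: the embedding layer's batch
standardisation is computed over **all tokens of a training minibatch
jointly** (`forward_batch`), not per slide.  Per-slide statistics would
subtract each slide's own mean and thereby erase exactly the
between-slide differences the model must learn; with joint statistics the
batch grand mean shifts both classes equally and the class contrast
survives.  Single-slide inference uses the running statistics.

**Training.** Binary cross-entropy on logits, AdamW (defaults lr 1e-5,
weight decay 1e-3, batch 32 slides, up to 150 epochs), linear warm-up for
5 epochs then cosine annealing over 95, early stopping after 20 epochs
without validation-AUC improvement, 4-fold cross-validation split at the
patient level; the fold with the best validation AUC is kept.  A
fine-tuning preset (lr 1e-3, weight decay 5e-4, batch 2, 50 epochs,
patience 10, warm-up 10 + cosine 20) adapts a trained model to
fresh-frozen material.  Slide probabilities may average several
independent cluster-sampling draws; patient scores are the arithmetic
mean of the patient's slide scores.

All networks run on a small in-repo reverse-mode autodiff core
(`pathofuse.nn`, float64 throughout); every primitive is verified against
central differences in the test-suite.

## Attribution

Integrated gradients on the pre-sigmoid logit with an all-zero token
matrix as baseline (both configurable).  The path integral is a midpoint
Riemann sum over a **graded partition** (cell boundaries `(k/n)^2`):
near an all-zero baseline many rectifier units switch and the layer
normalisation of a nearly-constant token set approaches degeneracy, so
the integrand is sharpest there and a uniform partition misses several
percent of the integral; grading restores sub-percent completeness at 128
steps while remaining exact for linear models at any step count.
LayerNorm uses eps 1e-3 for the same gradient-conditioning reason.
Completeness is reported on the slide with the largest |F(X) - F(X')|
(a relative gap against a near-zero denominator is meaningless).

Token attributions are averaged over embedding dimensions; tokens drawn
from the same source patch are averaged.  Slide maps repeat the cluster
sampling (500 draws in the reference protocol) and average each patch
over the draws in which it appeared; per-scale maps are emitted
separately.  Representative-patch selection ranks carrier slides by
descending probability and non-carriers ascending, then takes the top /
bottom `n` patches per slide by gradient value, ties broken by (slide_id,
row0, col0).

On planted-signal synthetic cohorts where 30% of carrier patches carry
the class signal, the top-gradient shortlist is enriched for
signal-bearing patches by ~1.4x the base rate.  Per-token gradients of a
tiny transformer carry substantial non-signal components, so near-perfect
per-patch recovery should not be expected at this scale; the tests assert
enrichment, not recovery.

## Microenvironment quantification

Nucleus instance/type maps (any segmenter; six PanNuke-style classes) are
ingested with majority-vote typing and a 5-pixel minimum size.  Each
nucleus gets 14 descriptors: 8 geometric (area, perimeter, eccentricity,
solidity, extent, major/minor axis, circularity = 4 pi A / P^2) and 6
gray-level co-occurrence statistics (ASM, contrast, homogeneity,
correlation, dissimilarity, entropy; 8 quantisation levels over the
nucleus's own intensity range, distance 1, four symmetric directions
averaged).  The published feature list is not public, so this canonical
set is the package's own choice and the names are configurable.

Two nuclei interact when their masks are 8-adjacent (equivalently,
overlap after 1-pixel dilation); the per-patch abundance of each of the
15 unordered distinct-type pairs is its contact count divided by the
patch's total cell count; same-type contacts are tracked separately.
Group comparisons use rank tests (Mann-Whitney for two groups,
Kruskal-Wallis beyond) and univariate logistic odds ratios on the
standardised feature with Wald 95% CIs.

## Multimodal fusion

Phenotypes are standardised on the training set: continuous fields
z-scored (missing -> training mean), categoricals one-hot with an
unknown-level bucket and a missing indicator.  The default schema covers
age, tumor size class, grade, node status, ER/PR/HER2/AR, Ki67 class and
personal/family cancer histories.

The mcVAE holds one encoder/decoder pair per modality (single hidden
layer, 256 wide for the 1536-d histopathology channel and 64 for the
phenotype channel by default; latent 32), a standard-normal prior, and
the objective

    L = beta * (KL_patho + KL_pheno) - sum_{i,j} log p(X_i | Z_j)

with all four (decoder, latent) combinations — intra-modal
self-reconstruction and inter-modal cross-reconstruction.  Latents use
the reparameterisation Z = mu + eps * sigma during training and collapse
to posterior means for inference; the fused patient representation is the
concatenation of the two posterior means, and a missing modality is
imputed by the observed channel's posterior mean (flagged).

Three likelihood/regularisation choices matter and were set by analysis
rather than convention:

1. **Learnable observation noise.**  With a fixed unit-variance Gaussian
   likelihood, a converged VAE encodes only directions whose data
   variance exceeds 1 — a clinically realistic class direction (image
   AUC ~ 0.85 means its variance is ~1.5x the noise floor, far below 1)
   is silently pruned.  Each reconstruction route therefore carries a
   learnable homoscedastic log-variance, and the self and cross routes
   are parameterised separately (the cross route's residual is
   irreducibly larger and must not inflate the self route's noise
   floor).  The log-variances are initialised at the marginal data
   variance because an adaptive-moment optimiser moves a log-variance
   only about one learning rate per step.
2. **beta = 0.25 by default.**  At beta = 1 the KL cost of keeping a
   marginal class direction approximately cancels its reconstruction
   gain, leaving retention to optimisation luck; the lighter prior
   weight keeps it decisively.  beta remains configurable.
3. **Fusion-head model selection on validation loss**, not validation
   AUC: at a few hundred patients the validation split is ~60 samples
   and an AUC-based early stop reliably freezes a near-random early
   epoch.

Training: AdamW, lr 5e-4, weight decay 5e-4, batch 32, up to 2000 epochs
with patience 100 on validation loss, warm-up 50 + cosine 50.  The head
is affine -> ReLU -> dropout 0.4 -> affine (hidden width configurable;
the published architecture table is not available), lr 5e-4, batch 60,
100 epochs, patience 10.  Shapley contributions use permutation sampling
(exact telescoping per permutation, efficiency in expectation), with the
linear-model closed form as the test oracle.

## Evaluation statistics

Rank-based AUC (ties half), percentile bootstrap 95% CIs (2000 resamples;
whole patients resampled when patient ids are supplied), largest
threshold reaching a target sensitivity, equal-count percentile
enrichment with odds ratios against the lowest bin (0.5 added to zero
cells), univariate logistic odds ratios with Wald CIs (separation flagged
unbounded), and the slides-per-patient experiment: for each n, sample n
slides per eligible patient without replacement, average their scores,
compute the patient-level AUC, and report the mean over (by default 1000)
repetitions.

## Synthetic data: what it emulates and what it does not

The generators provide every input the pipeline consumes, seeded and
bit-reproducible:

* **Embedding cohorts** — two-scale bags of isotropic Gaussian patch
  embeddings; carrier slides have a `signal_fraction` subset of patches
  mean-shifted by `signal_strength` (default 2.0, noise SD 1.0) along
  one hidden unit vector shared by the cohort.  The single-direction
  planted signal makes oracle recovery transparent: a logistic
  regression on bag means is the reference oracle.  Carrier fraction
  defaults to 0.3, mirroring a matched 1:2-3 case-control design;
  slides per patient follow a 1..6 distribution typical of hospital
  archives.
* **Phenotype tables** — mixed continuous/categorical fields with
  marginals patterned on a hospital case-control cohort; conditional
  generation gives exact population log-odds ratios (binary fields get
  +/- beta/2 on the logit scale; continuous fields a +beta SD shift in
  carriers).  Missingness is completely at random.
* **Multimodal cohorts** — the image modality is a *low-dimensional
  summary* (8-d by default) of what a trained slide model carries, with
  a label shift of 0.7 against noise SD 0.4.  This is deliberate: with
  n ~ 300 training patients, a class direction of realistic strength
  buried in a wide (64-d+) isotropic embedding falls below the
  Marchenko-Pastur detectability edge of the sample covariance, where
  *no* unsupervised compressor — mcVAE or PCA — can retain it; a wide
  design would test random-matrix geometry, not fusion.
* **Toy slides and nuclei masks** — blob rasters for the tessellation
  code, and disk-shaped typed nuclei with controllable densities, a
  target contact rate, 2-pixel separation between non-contact instances
  and a recorded ground-truth contact list.

None of these emulate histology texture, scanner characteristics, stain
variation, segmentation errors, or correlated phenotype structure.
Passing the suite shows that the machinery is correct and that each
component recovers signal it provably should; it says nothing about
clinical performance on real cohorts.

## Benchmark problem sizes

The test and acceptance experiments run at deliberately small scale,
chosen once: tiny transformer (32-d tokens, 2 blocks, 2 heads, 3x4 tokens
per scale) on 120 single-slide patients with a 90/30 patient-level split,
trained with the fine-tune-style rate (1e-3) for up to 30 epochs; mcVAE
recovery on 500 two-view samples with a 4-d shared latent; the fusion
benchmark on 600 patients (300 train / 300 test) repeated over 50 seeds;
50 random nuclei masks of <= 30 instances for the contact-detector
oracle.  The permuted-label control permutes labels across the whole
cohort before splitting, so its held-out AUC is evaluated against the
permuted labels (the proper null).

## Known limitations

* The autodiff core is single-threaded beyond BLAS and float64-only;
  full-size (1536-token, 12-block) training is out of scope — the
  default configuration is exercised at inference scale only.
* The attribution map emits per-scale values; no cross-scale physical
  registration is attempted.
* The mcVAE assumes the class-relevant structure is shared between
  modalities; strong channel-private structure is suppressed by
  cross-reconstruction (a property of the objective, demonstrated in
  the development experiments).
* `sens_spec_at_sensitivity` scans observed score thresholds only.
* The 14-feature list and phenotype schema follow field conventions, not
  a published table, and are configurable for that reason.
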