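# Methods

This note records the modelling choices, parameter conventions and numerical
decisions behind `metamatch`, and what the synthetic benchmark does and does
not establish about real data.

## The translation problem

A base model is trained on a large *meta-training* cohort to predict P
phenotypes jointly from anatomical MRI. A new study measures a *different*
phenotype y on a small cohort; only K participants (10–200) carry labels for
adaptation, and the remaining N − K are held out for evaluation. Because
behavioural and health phenotypes are mutually correlated, the base model's P
outputs form an informative K-independent representation of the new cohort,
and translation methods differ only in how they reuse it:

- **stacking**: kernel ridge regression on the top-M outputs (M = min(K, P));
- **finetune**: best-matching output node kept as head initialization, last
  two layers retrained;
- **transfer** (baseline): random head, last two layers retrained;
- **elastic net** (baseline): ignores the base model, refits on K
  participants from region-wise morphometric summaries.

## Normalization protocol

Every phenotype is z-scored. On the meta-training side the statistics come
from all meta-training participants; on the meta-test side, **from the K shot
participants only**, and those statistics are carried unchanged to the
held-out participants. Morphometric features are likewise z-scored with
K-shot statistics. ICV is z-scored with statistics from the meta-training
*training* split and that normalization is reused everywhere the network
sees ICV. Standard deviations use the n−1 (sample) convention throughout;
the choice is conventional and consistency matters more than the variant. A
variable with zero shot-sample standard deviation z-scores to 0 instead of
erroring, so tiny-K draws never crash a benchmark run. Evaluation happens in
the z-space defined by the K-shot statistics: Pearson r is invariant to this
choice; COD is not, and COD = 0 always means "no better than predicting the
evaluated sample's own mean" because the total sum of squares is taken about
that mean.

## Base model

Input volumes are divided by their own mean intensity (per image); at full
scale they are center-cropped to 160×192×160, dropping surplus voxels from
the high-index side when a margin is odd. The network is B convolutional
blocks (conv stride 1, size-preserving padding → batch-norm → 2×2×2/stride-2
max-pool → ReLU), the last block unpooled, then global average pooling, an
optional z-scored-ICV channel, dropout, and a dense head (equivalently a
1×1×1 convolution) with one output per phenotype. The pre-pooling extent is
floor-halved B−1 times (160×192×160 with 6 blocks → 5×6×5; 32×40×32 with 4
blocks → 4×5×4).

Two stock layouts are provided. Full scale: B = 6, channels
(32, 64, 128, 256, 256, 64), kernel 3 except the final kernel-1 block,
dropout 0.2 — the classic SFCN family layout. Desk scale (the tested
default): B = 4, channels (8, 16, 32, 16), kernels (3, 3, 3, 1), input
32×40×32. Training is SGD with momentum 0.9, weight decay 1e-3 (batch-norm
parameters exempt), batch 16, step LR decay (×0.5 every `lr_step` epochs),
and early stopping on a 20% validation split with the best-epoch parameters
restored. The loss is MSE averaged over *observed* target entries; masked
entries contribute exactly zero gradient. Desk-scale pretraining uses lr
0.03 for up to 16–18 epochs — at 800 meta-training participants this reaches
per-phenotype validation correlations of ≈ 0.85–0.94 in a few minutes on one
CPU, which is the regime the translation experiments need.

The implementation is plain NumPy with explicit backward passes;
convolutions are an im2col matrix product per layer and the packing /
pooling inner loops are numba-compiled. Float32 is the compute dtype;
gradient correctness is verified against finite differences in float64.
Evaluation-mode passes are pure functions of (parameters, inputs): dropout
off, batch-norm on running statistics.

"Last two layers" for finetuning means the final conv block (with its
batch-norm) plus the output head; everything earlier is frozen. Finetuning
therefore runs on cached frozen-trunk activations, which makes a 21-run
CV-grid finetune of a K=100 cell a sub-ten-second operation instead of
re-running the trunk each time.

## Adaptation methods

**Elastic net** fits on (λ_total, mixing) grids — 10 log-spaced decades
1e-4…1e2 crossed with mixing ratios 0.1…1.0, mapped to scikit-learn's
(alpha, l1_ratio) — by 5-fold CV on the K shots maximizing validation-fold
COD, then refits on all K. λ_total = 0 falls back to ordinary least squares.
An unpenalized intercept is included; with z-scored targets it is ≈ 0. A
fully-shrunk model predicts a constant; the harness scores its Pearson r as
0.

**Finetuning (both variants)** chooses the learning rate from
{1e-2, 1e-3, 1e-4, 1e-5} by 5-fold CV on the K shots (each candidate run
trains on the 4 in-folds with early stopping monitored on the held-out
fold), then trains a final model on all K with a fresh 80/20 early-stop
split, at most 50 epochs, patience 5. The transfer head is initialized with
centered small-variance (σ = 0.01) random draws; the meta-matching head with
the weight column of the argmax-COD output node (ties → lower node index).
CV fold assignment is shuffled K-fold under the cell seed and identical
across methods within a (K, repeat) cell.

**Stacking** ranks outputs by COD (descending, ties → lower index), keeps
M = min(K, P), and solves the KRR dual α = (G + λI)⁻¹y on the correlation-
kernel Gram matrix, λ ∈ {0, 1e-4, …, 1e3} by 5-fold CV on validation-fold
COD. A singular system at λ = 0 is skipped with a warning and the next λ is
used. Note the correlation-kernel Gram matrix built from M-dimensional
vectors has rank ≤ M − 1 (row-centering removes a dimension), so exact λ=0
interpolation exists only when M > K. With M = 1 (only possible when the
base model has a single output) a correlation across a length-1 vector is
undefined, and the model falls back to ridge regression on that single
prediction. No kernel centering or bias term is used; targets are z-scored.
Base predictions are computed once per cohort in evaluation mode and cached.

## Statistics

Method comparisons resample phenotypes and repeats jointly with replacement
(the difference matrix is repeats × phenotypes), recompute the mean
difference per resample, and report p = 2·min(P(≤0), P(≥0)) floored at
1/n_boot (default n_boot 1000). This treats both the phenotype and the
repeat as exchangeable units; with structureless cell noise it is
conservative, and its type-I error at α = 0.05 is verified to stay within
[0.01, 0.10] on simulated null data with phenotype-level structure.
BH-FDR is applied to the pooled p-vector across all K values, comparisons
and metrics. Cohen's D uses the df-weighted pooled sample variance;
|d| ≥ 0.8 is conventionally "large".

## Haufe-transform interpretation

For any adapted model, voxel importance is the sample covariance (n−1
denominator) between the model's prediction and each voxel's intensity
across the K participants; maps from repeated K-draws are averaged
voxelwise. Positive importance means higher intensity predicts a higher
phenotype score. The same construction against the P stacking inputs gives a
per-meta-training-phenotype importance vector; a correlation-scaled variant
is exposed as an option. Maps are written as NIfTI in the input grid's
space with whatever affine the inputs carry.

## Synthetic cohorts

The generator emulates exactly the statistical structure meta-matching
exploits, not MRI physics. Participants carry latent factors z ~ N(0, I_L).
A volume is a smooth head-like template scaled by a per-participant size
factor, plus one additive Gaussian-blob field per factor (3 blobs of radius
4–6 voxels by default, seeded placement) weighted by z, plus i.i.d. voxel
noise (σ 0.05 against a regional signal amplitude of 0.15 — a regional
intensity effect of ~15%, with every factor expressed in several
moderately-sized regions so that each is recoverable from images).
ICV is log-linear in the size factor. Phenotypes are y = Wz + ε with
per-phenotype noise variances; missingness is completely at random with a
floor of two observed values per phenotype. Morphometric tables are region
means/sums of the actual volumes over blob-aligned and null spherical
regions plus ICV, with measurement noise of 1.0× each readout's
across-participant signal sd — region summaries of a segmentation are
substantially noisier carriers of the latent signal than the full image,
which is the asymmetry that lets a large-cohort image model beat a K-shot
feature model.

`make_meta_benchmark` gives analytic control of phenotype overlap:
meta-training phenotype q loads a·z_q with a = √(1 − σ²_train) on its own
factor (mutually uncorrelated sources), and meta-test phenotype t loads
c·z_{q_t} with c = ρ_t/a, so corr(y_t, y_{q_t}) = ρ_t exactly and the
remaining variance 1 − c² is noise. Unreachable targets (c² above the noise
floor) raise. Participants are split disjointly; phenotype name sets are
disjoint by construction.

**What passing tests show** — that the implementations are correct, that the
K-shot protocol behaves as specified, and that in a regime with genuine
phenotype overlap and a well-trained base model the meta-matching orderings
(stacking > elastic net, finetune > transfer, improvement increasing with
overlap) emerge from the code. **What they do not show** — anything about
real T1 contrast: no deformation, bias fields, scanner effects, site
structure, non-linear phenotype relationships, or realistic missingness
mechanisms. Effect sizes on real cohorts are not predicted by the synthetic
margins.

## Benchmark harness and reproducibility

Every random decision flows from a master seed through
`numpy.random.SeedSequence` spawn keys: the (K, repeat) cell seed is
`child_seed(master, K, repeat)`, so any single cell is reproducible in
isolation and all methods see identical shot sets per cell (the paired
comparison statistics assume this). Shot draws are uniform without
replacement, unstratified. The 80/20 split uses round-half-up on the
training side, which reproduces both canonical split-size pairs
(26,573 → 21,258/5,315 and 36,461 → 29,169/7,292). Benchmark cells can be
checkpointed to JSONL and resumed; finetune-style cells dominate the cost.
A full rerun under the same master seed reproduces every evaluation record
bit-identically.

The tested desk-scale benchmark uses 800 meta-training participants,
600 meta-test participants, 10 meta-training phenotypes, 32×40×32 volumes,
K = 100 with 10 repeats, and a 5-point overlap sweep ρ ∈ {0.1, …, 0.9} —
sizes chosen so the complete end-to-end run (pretraining included) fits in
roughly ten minutes on one CPU while preserving the qualitative regime of
the large-cohort experiments.

## Known limitations

- The NumPy network targets desk-scale problems; full-scale (160×192×160,
  biobank-sized) pretraining is architecturally supported but compute-bound.
- The bootstrap unit (joint phenotype × repeat resampling) is one defensible
  choice among several; with few phenotypes it can be mildly conservative or
  anticonservative depending on the variance decomposition.
- Max-pool gradient ties route to the first maximum; with continuous data
  ties have measure zero.
- The elastic-net (λ1, λ2) pair is reported through scikit-learn's
  parameterization λ1 = αℓ, λ2 = α(1−ℓ)/2.
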