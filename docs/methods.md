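# Methods

## Problem and model

The classifier decides, from one axial key slice per DCE-MRI contrast
phase, whether a bladder tumor invades the detrusor muscle. The model
assumes the discriminative information is spatiotemporal: enhancement
kinetics (wash-in slope, peak phase, washout behaviour) and the spatial
relationship between tumor-type enhancement and the bladder wall. Static
intensity is deliberately uninformative in the synthetic data (both
classes share the same baseline), mirroring the clinical premise that
dynamics, not brightness, separate the classes.

### Tokenizer

Input X′ ∈ R^{H×W×5} is treated as a single-channel 3D volume whose depth
axis is the phase axis, so every 3D kernel mixes space and time. Each of
the three branches (kernels 1, 3, 5) applies

    conv3d(1→C1, k, same padding) → batch norm → ReLU → 2×2 spatial max-pool
    depthwise conv3d(C1, k, spatial stride 2) → pointwise 1×1×1 (C1→C2)
    → batch norm → ReLU → 2×2 spatial max-pool

for an exact ×8 spatial reduction (224 → 28, hence 784 features per
token). The phase axis is zero-padded and preserved through both layers —
saliency mapping slices it — and collapsed by a mean at the final
reshape, so a branch contributes C2 token rows. Token allocation is
(64, 128, 256) for kernels (1, 3, 5) with C1 = (16, 32, 64): larger
kernels carry more context channels, and the three blocks concatenate to
448 rows. A channel×phase token axis was considered and rejected: no
allocation summing to 448 divides by 5 phases, and collapsing the phase
axis at the reshape keeps per-phase activations available to Grad-CAM.

### Window attention

A WindowSpec (W, S, L) must satisfy (T−W) mod S = 0; the partitioner
rejects non-integral window counts rather than truncating. Defaults
W=64, S=48, L=8 give F=9 overlapping windows (overlap exercises fringe
fusion); boundary fringes clamp to the sequence edge. One learnable
context/auxiliary vector is shared across windows at initialization and
instantiated per window; its per-window state threads through the block
stack. Queries take (1+W) rows, keys and values share a single projection
over (1+W+2L) rows. Attention scales scores by √d_head; a
`raw_di_scaling` flag divides by d_head instead (the literal printed form
of the construction this follows). Each pre-norm block adds residuals and
a 2-layer ReLU feed-forward; overlapping window outputs scatter back to
the sequence by averaging per token position. After the last block the F
context outputs are averaged (unweighted, per the defining formula; a
learned-weight variant exists behind `learned_window_weights`, off by
default) and layer-normalized.

Depth 3, 8 heads (784/8 = 98 per head) and feed-forward expansion 6 size
the default model to 27.74 M trainable parameters, matching the published
~27.9 M budget to 0.6%; expansion 4 would undershoot it by ~26%.

### Head, loss, training

y_p = σ(W_o F_o + b_o); loss is mean binary cross-entropy with
probabilities clamped to [1e-7, 1−1e-7] (the loss is undefined at 0/1).
Invasion is the positive class; reports also carry per-class recall so
"sensitivity for the non-invasive class" is directly readable. Training
uses AdamW (defaults lr 1e-4, batch 8, ≤100 epochs, patience 10 — none of
these are externally specified), seeded shuffling, minority oversampling
with intensity jitter, and early stopping on validation loss with
best-weight restore. Weight initialization is fan-in-scaled Gaussian with
a fixed seed.

## Numerical engine

No array-autodiff framework is used: `invadenet.nn` is a compact numpy
layer library with hand-written reverse-mode gradients (im2col GEMM
convolutions, batch/layer norm, pooling with tie-splitting subgradients,
multi-head attention with the shared K=V projection). Correctness is
established by finite-difference checks at float64 in `tests/test_nn.py`
(≤1e-6 relative) and an end-to-end gradient check of the loss∘head
composition (≤1e-4). Max-pool ties share the gradient equally — a valid
subgradient that finite differences disagree with only at exact ties.
First-layer convolutions skip the input gradient unless phase adaptation
is active (it is never needed otherwise), roughly halving backward cost.

## Phantom generator

Each patient is a size-S axial slice with: dark lumen (intensity 40),
bladder-wall annulus (inner radius U(0.22, 0.30)·S, thickness
U(0.05, 0.08)·S, mild wall kinetics), a tumor half-disc on the inner wall
(radius U(0.09, 0.14)·S) protruding into the lumen, and background 60.
Enhancement is piecewise linear over the 5 phases: baseline 100, wash-in
slope to a peak phase, then linear washout. Class kinetics:

| class         | wash-in /phase | peak phase | washout /phase | wall depth |
|---------------|---------------:|-----------:|---------------:|-----------:|
| non-invasive  | 60 (SD 8)      | 2          | 22             | 0.15       |
| invasive      | 35 (SD 8)      | 3          | 2              | 0.85       |

"Wall depth" is the fraction of the wall thickness into which tumor-type
kinetics extend radially — the anatomical correlate of muscle invasion.
Per-patient wash-in slopes get Gaussian jitter (SD 8). Two distractor
blobs with kinetics drawn at random from either tumor family sit in the
ROI corners outside the wall: they decorrelate global enhancement
statistics from the label, so the classifier must localize enhancement
relative to the wall rather than average the image. Noise is Rician
(σ=5, magnitude of a complex-Gaussian-corrupted signal) plus Gaussian
(σ=3); with probability 0.05 the 60 s phase is dropped (4-phase sample).
Class fraction is 0.26 invasive (rounded exactly); identical
configuration and seed reproduce the cohort bit-for-bit.

What the phantom does *not* emulate: pharmacokinetic (Tofts-style)
enhancement, 3D multi-slice anatomy, scanner-specific artifacts, bias
fields, and anatomical variability beyond the stated geometry jitter.
Passing the learnability tests therefore shows the pipeline can recover a
planted spatiotemporal signal at desk scale — not clinical performance.

## Desk scale and the phantom study

CPU experiments use a structurally identical scaled model: 32×32 crops,
token allocation (16, 32, 64) with C1 = (6, 8, 12) (112 tokens × 16
features), windows W=16/S=12/L=4 (again F=9), 2 blocks, 4 heads,
expansion 2 (~9k parameters). The study protocol: 200-patient cohort,
stratified 6:1:3 split, normalization statistics from training tumor
voxels only, training with lr 1.5e-3, ≤40 epochs, patience 12, weight
decay 1e-3, input jitter 0.1, and random 90° rotations/flips. The
dihedral augmentation is exact (no interpolation) and label-preserving
because axial orientation in the phantom is arbitrary; without it the
desk model memorizes tumor positions instead of reading kinetics.

Ablations on the same cohort: "conv-only" replaces the attention stack by
token-mean pooling + layer norm; "attention-only" replaces the conv
tokenizer by a linear patch embedding (ViT-style, 80 patch tokens). A
label-shuffled control permutes training/validation labels and evaluates
against truthful test labels (chance AUC expected). At seeds 1, 2 and 7
the full model reached held-out AUC 0.97–1.00, ablations 0.92–0.99, and
the control ~0.5, with the full model strictly best each time; the
full-vs-ablation margin is a few AUC points, so occasional inversions at
other seeds are possible in principle.

## Statistics

AUC is the rank-based Mann-Whitney statistic with average-rank tie
handling and is verified against trapezoidal integration of the ROC curve
(1e-10). Confidence intervals are stratified bootstrap percentile
intervals (B=2000 by default). DeLong's test uses the structural
components estimator for the covariance of paired AUCs; Bonferroni
adjustment is min(1, m·p). Its calibration (type-I error within
[0.02, 0.09] at α=0.05, n=60) and agreement with a 10⁴-permutation paired
sign-flip oracle are asserted in the acceptance suite. Cohort percentages
round half-up to one decimal. Splits are seeded and stratified with
largest-remainder allocation; explicit counts (e.g. 115/20/49) override
the 6:1:3 ratio.

When model comparisons are reported with a ± dispersion, the assumed
source is seed-to-seed variation of training: the study helpers take a
seed argument, and a mean ± SD over several seeds is obtained by running
them repeatedly (the default harness runs one seed, since each training
run costs minutes on one CPU).

## Degenerate inputs and tie-breaks

Key-slice selection requires a non-empty tumor mask and takes the lowest
slice on area ties. Normalization requires pooled σ > 0. Window
partitioning, attention and fusion reject empty/non-finite inputs
explicitly. Grad-CAM returns a defined all-zero map for constant-zero
activations, normalizes per phase (matching independently scaled panels;
a global option exists), and defaults to the last convolution of the
mid-scale branch. Checkpoints carry an architecture fingerprint (config
hash) and refuse to load under a mismatched configuration; pipeline
artifacts are stamped with the run-config hash (output directory
excluded) so artifacts from different configurations cannot be mixed.

## Known limitations

The numpy engine is single-threaded BLAS-bound; full-scale (224×224)
training is out of reach on one CPU, so learnability claims are made at
desk scale only. N4 bias-field correction is an external preprocessing
hook, not implemented. Automatic bladder segmentation is out of scope;
ROIs come from the generator (or, for real data, a reader). The
conditional-GAN minority augmentation mentioned in the source context is
replaced by oversampling + classical augmentation.
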