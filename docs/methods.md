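# Methods

This note documents the models and procedures `neurofuse` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Voxel-wise intensity projections

A subject's resting-state decomposition is a stack of K aligned component
spatial maps (intrinsic connectivity networks).  The three projections
collapse the stack per voxel: `max_icn = max_k x_k`,
`abs_min_icn = |min_k x_k|`, `max_abs_icn = max_k |x_k|`.  They satisfy
`max_abs = max(max_icn, abs_min_icn)` exactly, are permutation-invariant
in k, and are positively homogeneous (projecting c·x equals c times the
projection for c > 0).  Projections operate on raw component values;
masking and normalization are applied downstream, so any standardization
of the component maps is the caller's responsibility.  An optional argmax
diagnostic reports which component won at each voxel, breaking value ties
toward the lowest component index.

## Masking and normalization

One binary mask per subject is derived from that subject's gray-matter
map by a strict comparison (`density > 0.03`) and applied to all of the
subject's channels.  Min-max normalization uses the within-mask minimum
and maximum only and writes 0 outside the mask.  A constant in-mask
volume (zero range) yields all zeros with a warning instead of an error,
so batch runs survive degenerate inputs.  In the fused construction the
normalization runs twice by design: once per modality after masking, and
again after each square/product, so all three channels span [0, 1].

## Spectral baselines

ALFF is the mean one-sided FFT amplitude over bins whose center frequency
lies in the closed band [0.01, 0.08] Hz (the conventional low-frequency
band; configurable).  fALFF divides the band amplitude sum by the
amplitude sum over all positive frequencies up to Nyquist, with 0/0
defined as 0, giving a scale-invariant value in [0, 1].  Series are
demeaned before the transform; since the DC bin is excluded from every
sum, demeaning preserves the analytic behavior of a pure sinusoid (all
mass in one bin, so an on-bin in-band sine gives fALFF exactly 1).
Least-squares linear detrending is available (`detrend_method="linear"`)
for data with scanner drift; it is not the default because the fitted
slope of a finite sampled sinusoid is nonzero, so it leaks a small
fraction of oscillatory amplitude across bins and breaks the exact
single-bin property.  No global-mean division is applied; downstream
min-max normalization supersedes it.

## Classifier and training protocol

The classifier is an AlexNet-3D-lineage stack: repeated
[conv3d → batch norm → ReLU → (max pool at designated stages)] blocks,
adaptive average pooling to a fixed spatial size, then
FC → ReLU → dropout → FC → ReLU → dropout → linear logits.  Defaults:
five conv blocks with filters (64, 128, 192, 192, 128), pooling after
blocks 1, 2 and 5 (kernel 3, stride 2), dropout 0.5, adaptive pool to
1×1×1, FC widths (64, 32).  Kernel/stride/padding defaults to 3-2-1; the
searched alternatives are 3-2-1 and 5-2-0.  Adaptive pooling makes the FC
width independent of the input grid, so the same architecture accepts the
53 × 63 × 52 acquisition grid and small synthetic grids; an input too
small for the conv/pool stack raises an error naming the failing stage.

The engine is a self-contained NumPy implementation: im2col 3D
convolution, batch normalization with running statistics, inverted
dropout, Adam (bias-corrected), and softmax cross-entropy, all with
hand-written backward passes verified against finite differences in the
test suite.  Weights are He-normal from a recorded seed, so builds are
bit-reproducible; eval-mode forwards are deterministic.

Training minimizes cross-entropy with Adam.  A scheduler halves the
learning rate when validation accuracy fails to improve by more than 1e-4
for 5 consecutive epochs (the halving factor is fixed; the plateau window
is this package's choice).  Early stopping ends training after 20 epochs
(default) without validation improvement, and the parameters from the
best-validation epoch are restored.  One master seed fans out to the
split, initialization, and batch-order streams (fold f uses seed +
1000·f for training and init_seed + f for weights).

## Cross-validation and metrics

Splitting is stratified Monte Carlo: each fold is an independent random
draw of validation and test cohorts (not a partition), with per-class
counts allocated by largest remainder so proportions match the cohort
within one subject.  With the floor rule, validation and test each get
⌊n / n_folds⌋ subjects — 466 subjects at 8 folds give (350, 58, 58).
Designs that deviate from the floor rule are expressed with explicit
cohort sizes (95/95 out of 730 leaves 540 for training).

Metrics per fold, on a 0–100 scale: accuracy; balanced accuracy (mean of
per-class recalls); F1, precision and recall **macro-averaged** (the
averaging scheme changes the numbers, so it is stated prominently); AUC
from softmax scores — positive-class ROC area for two classes (positive =
AD), macro one-vs-rest for three.  Every class must appear in the test
set or evaluation raises.  Fold aggregation reports the arithmetic mean
and the sample standard deviation (ddof = 1), formatted "m ± s".  Model
comparison pools correct/incorrect test counts across folds into one 2×2
table per model pair and applies Pearson's chi-squared with 1 df and no
continuity correction.  A chi-squared comparison of AUC values is not
implemented: AUC is not a count, so the test is undefined as described.
Hyperparameter search enumerates learning rates {1e-1 … 1e-5}, batch
sizes {4, 8, 16, 32, 64} and the two kernel combinations, maximizing mean
validation accuracy; test cohorts are touched only once, afterwards.

## Saliency

Guided backprop computes the gradient of the chosen class logit with
respect to each input channel, zeroing the backward signal at every ReLU
where the forward activation was ≤ 0 or the incoming gradient is
negative.  With no ReLU in the network it reduces exactly to the input
gradient — the analytic oracle in the tests.  Cohort summaries mask each
per-subject map, smooth at FWHM 10 (interpreted in millimeters by
default; a unit flag exists because conventions vary), and average.  By
default maps are reduced to magnitudes before averaging so opposite-sign
attributions do not cancel; signed averaging is a flag.  The target class
defaults to the subject's true label.  Thresholding (default in-mask
quantile 0.9) happens only at visualization time; montages render
sagittal/coronal/axial slices and also write the thresholded map as
NIfTI.

## Synthetic cohorts

The generator emulates exactly what the pipeline needs and no more:
aligned per-subject gray-matter volumes, component stacks, optional
band-limited time series, and labels.  Gray matter is a fixed template of
smooth 3D Gaussian blobs at fractional coordinates (so any grid ≥ 8
voxels per axis works) over a broad background blob; the first two blobs
are the designated "atrophy" sites, scaled by (1 − gm_effect) in AD and
(1 − gm_effect/2) in MCI.  Each component map has a positive and a
negative Gaussian lobe, so the max- and |min|-projections carry distinct
information.  The two designated components pin a lobe (one positive, one
negative) onto the atrophy sites, and their amplitude is
(1 + icn_effect) in CN, halfway in MCI, baseline in AD — disease loses
network amplitude, matching the observation that the cognitively normal
maps carry the higher in-mask maxima.  This polarity also keeps the
class signal visible in the fused s·v channel after per-subject
re-normalization: a third, non-designated component is pinned onto a
non-atrophy gray-matter blob so the in-mask maximum of s·v is a
class-independent anchor rather than the atrophy site itself.  Voxel
noise is independent Gaussian (sd 0.05 by default); spatial noise
correlation is not modeled.  Time series are single in-band sinusoids on
an exact FFT bin with amplitude proportional to the subject's
max-absolute component signal, plus white noise.

Determinism: one cohort seed; subject i uses sub-seed
(seed · 1,000,003 + i) mod 2³¹.

What the generator does **not** emulate: anatomy (the blobs play the role
of hippocampus/amygdala but make no anatomical claim), hemodynamics,
scanner artifacts, head motion, registration error, site effects, or
realistic effect sizes.  Passing tests therefore demonstrate that the
pipeline is implemented correctly and can recover strong, well-localized
class signal; they say nothing about accuracy attainable on clinical
data.

## Problem sizes for the shipped runs

The test suite and the acceptance script run the full pipeline at desk
scale, chosen once as realistic for a CPU-only demonstration: cohorts of
120 subjects (60 AD / 60 CN) on a 24³ grid with K = 8 components,
gm_effect 0.4, icn_effect 1.0, three repeated folds with explicit 20/20
validation/test cohorts, and a compact model configuration
(`small_model_config`: conv filters (8, 16, 32), 3-2-1, no extra pooling,
adaptive pool 1³, FC 64/32), trained at learning rate 1e-3, batch 8, ≤ 40
epochs, patience 10.  The full-scale defaults (53 × 63 × 52, K = 53,
five conv blocks) are exercised for shape correctness but not trained in
the shipped runs.

## Known limitations

- The NumPy engine is single-threaded and unsuited to full-scale training
  of the default architecture; it is built for correctness, testability
  and transparency of the backward pass.
- Batch-norm running statistics make train/eval forwards differ by
  design; with very small cohorts this can leave a well-ranked but
  miscalibrated decision threshold (visible as AUC ≫ accuracy).
- Regression heads, nested CV, attention/learned fusion, SHAP, and
  registration/resampling between grids are out of scope; inputs are
  assumed pre-aligned on one grid.
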