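# Methods

This note records the models, algorithmic conventions and design choices
behind `keranet`, in the order data flows through the pipeline.

## Problem and data model

The task is binary classification of dermoscopy images into actinic
keratosis (AK, the positive class) versus non-actinic keratosis (NAK).
Metadata readers support the HAM10000 dialect (`image_id`/`dx` CSV;
`akiec` → AK, `bkl` → NAK, everything else dropped) and the ISIC-2019
one-hot ground-truth dialect (`AK`/`BKL` columns). NAK is operationalized
as benign keratosis-like lesions (`bkl`) only; that class alone matches
the 1099-image NAK count of the reference corpus. Duplicate image ids are
a hard error, record order follows CSV row order, and all shuffling
happens downstream under explicit seeds, so data input is a pure function
of file bytes.

## Preprocessing

sRGB images are converted to CIE L\*a\*b\* under the D65 reference white
(scikit-image's standard sRGB→XYZ→Lab transform). CLAHE is applied to an
8-bit quantization of the L\* channel only; a\* and b\* pass through
bit-identically. The CLAHE implementation is the classical algorithm:

* the image is divided into a `tile_grid` (default 8×8) of tiles;
* each tile's 256-bin histogram is clipped at
  `clip_limit × tile_area / 256` (default clip factor 2.0) and the
  clipped excess is redistributed uniformly over all bins;
* each tile's mapping is the CDF of the clipped histogram evaluated at
  the *bin midpoint* (`cdf − hist/2`), scaled to [0, 255];
* pixels are remapped by bilinear interpolation between the mappings of
  the four surrounding tile centers.

The midpoint rule makes the mapping unbiased: a constant tile maps to
itself up to one quantization level (for tiles of area A the deviation is
bounded by ≈ 255·clip/(2·A/256) ≈ 1 level at the default geometry),
whereas the usual upper-edge CDF rule shifts constants upward. Mappings
are non-decreasing by construction (successive differences are
non-negative histogram sums). Clip limit and tile grid are not dictated
by the protocol this pipeline follows; the defaults are common CLAHE
practice and both are exposed in `PreprocessConfig`.

Enhancement runs at native resolution; resizing (bilinear, to the network
input size) happens afterwards, so the tile geometry is independent of
the target size. The final tensor is scaled to [0, 1]. The whole module
is deterministic.

## Augmentation

One random affine transform per image: rotation U(−20°, 20°), x/y shifts
U(−0.1, 0.1) of the image size, isotropic zoom U(0.9, 1.1), horizontal
and vertical flips each with probability 1/2. Magnitudes are conventional
defaults (the protocol names the operations but not their ranges) and all
are configurable. The draw order is fixed, so a seed determines the
stream. Augmentation is applied to training folds only — validation must
estimate generalization — and operates on the preprocessed tensors (the
affine transforms commute with per-image enhancement well enough that
enhancing once up front is preferable to re-running CLAHE per epoch). An
optional minority-oversampling factor in `TrainConfig` repeats AK
training examples; it is off by default because no resampling rule is
part of the reference protocol.

## Architecture

`NetworkSpec` describes the network declaratively; `build_network`
realizes it and cross-checks the framework parameter count against the
closed-form count (depthwise k²·C, pointwise C·F, standard k²·C·F, batch
norm 2·C, dense C·F+F; convolutions carry no bias because batch norm
follows each one). "15 layers" counts convolutions: 1 standard conv plus
7 depthwise-separable blocks × 2 convs, consistent with counting the full
MobileNet as a 28-convolution network. The truncation point is exposed
(`truncate_after_block`, 1–13) because alternative layer-counting
conventions would place the cut elsewhere; the default stops at 512
channels, before the five 512→512 repeats and the 512→1024 blocks that
hold most of the full network's parameters (closed-form: 538,946 vs
3,209,026 trainable parameters, a 5.95× reduction). ReLU (not ReLU6)
follows every convolution; the head is global average pooling → dropout
0.25 → dense(2) with bias → softmax. No pretrained weights are used
anywhere: initialization is seeded He-normal for convolutions and
Glorot-uniform for the dense layer.

## Training

The NumPy training loop implements Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7 —
only the learning rate is part of the protocol), categorical
cross-entropy on one-hot targets with the numerically fused
softmax-gradient form, and mini-batches of 32 for up to 30 epochs
(defaults; the scaled-down study below uses 10).

**Learning-rate schedule.** Validation accuracy is monitored;
"improvement" means strictly exceeding the best value so far (ties count
as stagnation, no min-delta, no cooldown). After 2 stagnant epochs the
rate is halved and clamped at 1e-5, and the stagnation counter resets.
The trace therefore satisfies lr(t+1) ∈ {lr(t), max(lr(t)/2, 1e-5)}.

**Checkpointing.** After every epoch the weights with the highest
validation accuracy so far are retained (first epoch wins ties); the
fold's reported predictions come from those weights applied to the
untouched validation fold. Note the statistical consequence: selecting
the best of E noisy epoch accuracies is upward-biased at chance level, so
a no-signal dataset reports mean validation accuracy somewhat above 0.5
(empirically ≈ 0.53–0.64 for 10 epochs and 24-image folds). This is
inherent to best-checkpoint reporting, not a leak: the δ=0 control band
in the acceptance study accommodates it.

**Batch normalization at inference ("precise BN").** Exponential running
averages (momentum 0.9) lag the weights badly when an epoch contains only
a handful of optimizer steps, which decouples inference-mode predictions
from training-mode behavior. Before each validation pass the network
therefore re-estimates every batch-norm layer's population statistics
with one forward pass over (up to 256 of) the training images under the
current weights — the population-statistics inference scheme of the
original batch-norm formulation. Without this, small-epoch runs show
near-perfect AUC but chance-level thresholded accuracy.

**Folds.** Stratified k-fold (default k=5): within each class, members
are shuffled under the seed and dealt round-robin; the dealing offset
rotates between classes so overall fold sizes also differ by at most one.
Stratification is a deliberate strengthening of plain random partitioning
— with a 327:1099 imbalance, unstratified folds risk class-starved
validation sets — and `stratified=False` restores plain random splits.
Every record is validated exactly once.

**Seeding.** One training seed fans out through `numpy.random.SeedSequence`
spawning to per-fold seeds and, within a fold, to initialization,
augmentation and shuffling streams; the CLI derives per-component seeds
from its single global seed the same way. Reports embed all seeds, and
identical seeds reproduce reports bit-for-bit.

## Metrics

All metrics treat AK as positive. Cross-entropy uses the natural
logarithm with probabilities clipped to [1e-7, 1−1e-7]. MCC returns 0
when any margin of the confusion matrix is empty (the standard
convention, keeping the statistic total). AUC is computed in the
Mann–Whitney pair-counting form via midranks, which equals the
trapezoidal area under the ROC curve built at distinct thresholds; ties
contribute one half. Fold aggregation reports mean ± t₀.₉₇₅,k₋₁·sd/√k
(sample sd); the Student-t interval is the defensible small-k choice for
five folds. Thresholded metrics use p ≥ 0.5 unless overridden.

## Synthetic corpus

Each image is a smooth low-frequency skin-tone field plus one elliptical
lesion with random center, axes (18–32% of the image side) and rotation.
Class signal scales linearly with δ: AK lesions gain a red-brown hue
shift (+0.12, −0.05, −0.08 in RGB) and Gaussian high-frequency roughness
of amplitude 0.10·δ; NAK lesions gain a waxy low-frequency sheen and a
boundary that sharpens with δ. At δ=0 every class term vanishes, so the
two classes are draws from one distribution and chance is the best
possible accuracy; at δ=1 the hue separation alone makes the Bayes error
effectively zero. Images are written as PNG (byte-deterministic across
codecs) with a HAM10000-dialect metadata CSV. The generator emulates
class structure, imbalance (via `imbalance_preset`, 327:1099) and seeded
reproducibility — not clinical appearance: there are no dermoscopy
artifacts (hair, rulers, gel interfaces), no camera variation and no
intra-class diagnostic subtypes. Passing tests on this corpus therefore
demonstrate that the pipeline's machinery is correct and learnable
signals are learned, not that real-data accuracies transfer.

## Scaled-down reference study

The acceptance study uses 60 images per class at 64×64, a proportionally
truncated network (3 blocks at width multiplier 0.25, ≈ 5.6k parameters),
five folds and 10 epochs — sizes chosen so the full double study (δ=1
and δ=0) completes in about two minutes on one CPU while exercising
every stage of the pipeline. At δ=1 the study reaches mean validation
accuracy 1.0 across seeds; at δ=0 it stays within the chance band.

## Known limitations

* The NumPy training loop is single-threaded and orders of magnitude
  slower than a GPU framework; full-scale HAM10000 runs are possible but
  slow (the code favors auditability).
* Cross-corpus duplicate removal (HAM10000 vs ISIC) is not implemented.
* No lesion segmentation, hair removal or color constancy; the reference
  protocol describes none.
* `cross_entropy` clips rather than raising on p ∈ {0, 1}; reported loss
  therefore saturates near 16.1 nats per maximally wrong prediction.
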