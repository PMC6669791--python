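# Methods

This note documents the models, procedures and numerical choices behind
`bibnet`, and what the synthetic phantom experiments do and do not show.

## The segmentation model

BibNet is a fully convolutional encoder–decoder for 3-D volumes whose
output spatial shape equals its input shape, so a whole CT volume is
segmented in one forward pass instead of tiled patches. Its layout is a
"bib"-shaped grid over resolution levels:

* an **encoder column**: residual blocks per level, separated by 2×2×2
  stride-2 pooling convolutions, with the filter width doubling at every
  level (8, 16, 32, 64, 128 at the default five levels);
* a **lateral row** on every level: residual blocks fed by the same-level
  encoder output plus a strided projection from the level above and a
  transposed-convolution projection from the level below, so features of
  adjacent scales are mixed at every resolution;
* a **decoder column** built bottom-up: each stage upsamples by a stride-2
  transposed convolution, concatenates the same-level lateral output, and
  applies residual blocks;
* a 1×1×1 convolution with an independent sigmoid per organ channel.
  Multi-organ output is multi-label; channels are not forced to be
  mutually exclusive.

A convolutional block is `dropout → 3×3×3 padded convolution → PReLU →
batch normalization`, in that (unconventional, but deliberate) order; a
residual block is two such blocks plus an additive skip, with a 1×1×1
projection when the channel count changes. PReLU has one learnable slope
per channel (initial 0.25). Weights are seeded He-uniform.

### Pinning the default configuration

Two printed properties identify the reference instance: ~7.5 million
trainable parameters, and a 484-voxel receptive field per axis for
neurons in the deepest encoder layer. The receptive field of the encoder
path is analytic: a kernel-*k* layer seen at cumulative stride *S* widens
the field by (k−1)·S. With L = 5 levels and c_l 3×3×3 convolutions on the
encoder path at level l,

    RF = 1 + 2·Σ_l c_l·2^l + (2^(L−1) − 1).

Encoder residual blocks (3, 3, 3, 4, 4) give Σ c_l 2^l = 234 and RF = 484
exactly. Lateral blocks (1, 1, 1, 1, 2) and decoder blocks (1, 1, 1, 1)
then bring the parameter count to 7,515,147 (0.2 % above 7.5 M). Both
quantities are recomputed from the built network in the test suite and in
`scripts/acceptance.py`.

Inputs whose extents are not divisible by 2^(L−1) are symmetrically
zero-padded inside `forward` and the output cropped back, preserving the
full-image contract for arbitrary volumes.

### Baseline U-Net

The comparison network is a 3-level valid-convolution U-Net: encoder
filters 32/32, 64/128, 256/256; decoder 128/128 and 64/64; 2×2×2 max
pooling; nearest-neighbour upsampling; centre-cropped skip concatenation;
ReLU activations. Each axis shrinks by 40 voxels end to end and
admissible inputs are multiples of 4 with extent ≥ 44; the module raises
with that minimum named rather than guessing. (A printed input size of
68×68×64 cannot be reproduced by symmetric valid-convolution arithmetic
with isotropic pooling — 68 − 40 = 28 works per axis only when the axis
obeys the mod-4 rule, which 64 does but the stated z-output does not
match; the implementation documents its own arithmetic instead of
claiming that size.)

Patch-wise inference shifts the input window by exactly the output-patch
size so output tiles abut. Because every output voxel of a
valid-convolution network depends only on its own input window, and tile
offsets are kept multiples of the total pooling stride (4), the assembled
result is *bitwise equal* to a single large pass on the covered interior;
the test suite asserts equality with zero tolerance.

## The numerical engine

No deep-learning framework is used: the package contains a small
reverse-mode autodiff core (`bibnet.nn`) written on numpy, with 3-D
convolution/transposed convolution implemented as a loop over kernel
taps, each tap a batched BLAS matmul. Only the padded input is retained
for the backward pass (tap windows are re-sliced), keeping peak memory at
roughly one volume per layer. Gradients of every layer are verified
against central finite differences in the test suite.

The optimizer is Nesterov-accelerated Adam (Nadam) with the published
default moments (β₁ = 0.9, β₂ = 0.999, ε = 1e-8); the update is checked
against an independent evaluation of the recurrence on a scalar
quadratic to 1e-10.

## Training procedure

* **Loss**: the soft Jaccard loss J = 1 − (Σp·y + ε)/(Σp + Σy − Σp·y + ε)
  with ε = 1e-5, averaged with equal weight over organ channels, drives
  back-propagation. The Dice loss of the binarized prediction scores
  models during validation ranking.
* **Learning rate**: linear decay from 1e-2 to 1e-5 across the planned
  epochs, clamped at the floor afterwards.
* **Patch sampling**: a weighted mixture of an entropy sampler (256-bin
  uint8 histogram entropy above a threshold, default 2 bits), two shell
  samplers (patch centre within 20 or 40 mm of a structure surface, true
  Euclidean millimetres under anisotropic spacing) and a mask sampler
  (patch must intersect the structure). Admissibility anchors on the
  patch centre; equal weights by default; rejection budget 10,000 draws.
* **Tournament selection**: eight independently initialized networks are
  trained in schedule; the worse half by validation score is dropped at
  epochs 20/40/80 (8 → 4 → 2 → 1) and the survivor continues with early
  stopping (patience 10 epochs) as the convergence criterion. Each
  network draws from its own seeded sampler stream; whether the
  population should share one batch sequence is unspecified upstream, and
  independent streams were chosen for simplicity and parallelism.
* **Batch-norm statistics**: training on steered patches biases the
  running mean/variance toward organ-rich crops, which differ sharply
  from whole-volume statistics (mostly air). Two measures compensate:
  mid-training validation computes batch statistics from the evaluated
  volume itself (dropout off, deterministic), and after training a
  "precise-BN" recalibration pass re-estimates the running statistics as
  the exact average of per-volume batch statistics over the training
  volumes. Without this, a patch-trained network can predict empty masks
  on full volumes.
* The single-network `fit` helper finishes with whole-volume optimization
  steps before recalibration; the tail epochs align border behaviour and
  normalization statistics with full-image inference.

## Phantom data

Real thorax CT with curated structure sets is not shippable, so every
stage is exercised on seeded synthetic phantoms: an ellipsoidal
soft-tissue body on air, two low-intensity lungs, a heart between them
and two anterior breasts, with HU-like class means (air −1000, lung −700,
fat −100, soft tissue 40), additive Gaussian noise (default SD 20), and
per-case uniform jitter (±8 % radii, ±3 mm centres) standing in for
anatomical variation. The default grid is 64×64×32 voxels at
(2.34, 2.34, 3.0) mm — the same working spacing the preprocessing chain
produces, scaled down in extent so a reduced network trains on one CPU.
Default organ placements were chosen so that all organ masks stay inside
the body across jitter (validated over 800 jittered cases); a spec whose
organs cannot fit raises a geometry error rather than clipping.

What passing phantom tests shows: the losses, samplers, optimizer,
selection, inference and metrics interact correctly end to end, and the
model class can represent and learn the mapping. What it does not show:
performance on real CT — phantoms have no fat/gland texture, no diffuse
breast boundary, no arm-position variation, no contrast agent, and their
organs are ellipsoids. Reported Dice values on phantoms are therefore
pipeline diagnostics, not clinical claims.

## Metrics and evaluation

Dice and Jaccard follow their set definitions on voxel masks; a pair of
empty masks yields NaN (flagged), never a silent 0 or 1. Surfaces are the
centres of mask voxels with at least one 6-neighbour background voxel
(out-of-grid counts as background). The RMS surface distance is the
*directed* prediction→reference root-mean-square of nearest-point
distances, matching the printed formula; the symmetrized mean is also
available. The Hausdorff distance is symmetric. Nearest-point queries use
a k-d tree but are required by the tests to agree with O(n²) all-pairs
brute force to 1e-6 mm.

Cohort reports carry one row per case and organ; a case is excluded
per-organ with an explicit reason when either mask is empty. Summaries
report the median (robust to single failures) with the mean alongside.
Model comparison uses the classical paired two-tailed t-test per organ
and metric, with the Bonferroni-adjusted level α = 0.05/3 = 0.0167 for
the three-organ multiple-comparison problem; raw p-values are always
reported.

## Post-processing

Working-resolution probability maps are resampled to the CT geometry by
trilinear interpolation, Gaussian-smoothed with a physical sigma
(default 1.5 mm, divided by per-axis spacing), thresholded at 0.5, and
reduced to the largest connected component (26-connectivity, ties broken
toward the lowest label). Smoothing acts on probabilities *before*
binarization — whether it should precede or follow binarization is not
specified upstream; pre-threshold smoothing avoids re-binarization
artifacts. An empty post-processed mask returns with a warning flag and
is excluded from scoring rather than scored as zero.

## Preprocessing conventions

Resampling evaluates trilinear interpolation at the voxel centres of the
target geometry. Out-of-domain samples use edge-value extension (avoids
synthesizing air inside the body at borders); the output shape is
`ceil(shape·spacing/target)` so physical extent is never discarded; the
origin (first voxel centre) is preserved. Masks are interpolated as 0/1
fields and re-binarized at 0.5. The uint8 inference format maps a
configurable window (default −1024..1024 HU) linearly to 0..255 with
half-up rounding.

## Problem sizes used in tests

The suite trains only reduced instances: a 2-level, base-8 network
(~66 k parameters) on eight 64×64×32 phantoms with 250 optimization
steps (200 patch steps at 48×48×24, then 50 whole-volume steps,
learning-rate schedule spread over 7 planned epochs), reaching full-volume
training Dice ≥ 0.90 on all organs; micro instances (base 2–4 filters,
16³–32³ volumes) exercise the tournament loop and the end-to-end
pipeline. The full five-level configuration is built and analysed
(parameters, receptive field) but not trained in the tests.

## Known limitations

* Single-device, float32, batch sizes 1–2; no mixed precision, no
  multi-GPU, no data-parallel tournament.
* The exact per-level wiring of the original figure is reconstructed
  from its caption under two hard constraints (parameter count,
  receptive field); other wirings satisfying both exist in principle.
* `rms_surface_distance` is directed by definition here; comparisons with
  symmetric implementations elsewhere must account for that.
* The phantom generator emulates geometry and first-order intensity
  statistics only (see above).
* DICOM/DICOM-RT I/O is out of scope; volumes and masks travel as NIfTI
  with a JSON organ→filename sidecar.
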