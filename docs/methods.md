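# Methods

This note documents the models and procedures implemented in `podseg`, the
parameters that matter, the numerical conventions, and what the synthetic
benchmark does and does not demonstrate.

## Continual segmentation protocol

Foreground classes are partitioned into an ordered schedule `C^1 .. C^T`
(background is always label 0).  The step-`t` dataset `D_t` contains every
case whose mask has at least one pixel of a class in `C^t`; cases containing
classes from several steps appear in every matching `D_t`, and within `D_t`
all labels outside `C^t` are remapped to background.  At step 1 training is
plain pixel cross-entropy on the ground truth — the distillation and
pseudo-label machinery requires an old model, which does not exist yet.  For
`t ≥ 2` the step-`t−1` model is frozen (its parameter hash is checked in
tests), its output head is copied and extended by one channel per new class
(new rows zero-mean, σ = 0.01, seeded; old logits are bit-identical after
extension), and the objective becomes `L_pseudo + λ·L_localPOD`.

## Local POD distillation

The POD embedding of an `H×W×C` feature map concatenates the width-averaged
slices (one `C`-vector per row) and the height-averaged slices (one
`C`-vector per column), each flattened spatial-major / channel-minor, width
block first.  The local variant tiles the map into `s×s` regions for every
scale in `S` with half-open boundaries `⌊iH/s⌋..⌊(i+1)H/s⌋` (regions may
differ by one row/column when `s` does not divide the extent), embeds each
region, and concatenates region vectors row-major, scales in listed order.
The stored vector therefore has length `C·Σ_s s·(H+W)`; the loss is the
squared Euclidean norm of the embedding difference averaged over tapped
layers, so any fixed, consistent flattening yields the same value.  The
tapped layers are the per-stage cross-modality fusions plus the decoder's
pre-logit feature map, configurable by name.  Default scales are `(1, 2, 4)`
— the whole map, quarters, and sixteenths — a small set that captures both
long- and short-range statistics.  The pooling statistic is the arithmetic
mean, and the embedding operator is linear, which gives the distillation
term a cheap exact adjoint in the backward pass.

The equations are two-dimensional; for volumetric backbones the intended
treatment is per-axial-slice distillation averaged over slices.  The 2-D
path is the implemented and tested surface.

## Pseudo-labeling under background shift

Per pixel of a step-`t` case, the target is: (a) the ground-truth label if
it belongs to `C^t`; (b) for ground-truth background, the old model's argmax
class `c*` among old foreground classes if the old model's full-distribution
entropy is below `τ_{c*}`; (c) ignored if the old model is uncertain
(`u ≥ τ_{c*}`, or no threshold exists for `c*`); (d) background if the old
model itself says background — the old model is the only authority on
non-current content, and such pixels are not candidates for `v`.  The
ground-truth branch keys on the ground-truth mask, not on current-model
predictions, so targets never depend on the network being trained.

Thresholds are computed once, before the step, as the median entropy (nats,
natural log, `0·ln 0 = 0`; even pools use the midpoint of the central order
statistics) over all pixels of `D_t` the frozen old model arg-maxes to each
class.  Classes the old model never predicts get no threshold; pixels cannot
be arg-maxed to them, and a missing threshold encountered anyway ignores the
pixel and logs a warning.

`v` is the fraction of candidate pixels (ground-truth background, old-model
argmax an old foreground class) whose pseudo-label was accepted, computed
per image; it weights that image's cross-entropy, which is normalized by the
number of non-ignored pixels.  An image with no candidates at all (for
instance, one containing no old-class tissue) keeps weight 1 rather than
`v = 0` — the loss there degenerates to plain supervision; zeroing it would
discard the image's ground truth entirely.  Predicted probabilities are
clamped at 1e-12 inside the log.  Batch losses average the per-image losses.

## Segmentation network

A desk-scale analog of a four-stream residual encoder with
atrous-spatial-pyramid-pooling (ASPP) context and a light decoder.  Each
modality has its own encoder: a stride-2 stem convolution (3×3 at desk
scale) and `n_stages` stages of two residual units (widths
`base_width·2^s`, stride 2 entering every stage past the first).  How the
parallel modality streams merge is an open design choice; here the
per-stage features are concatenated across modalities and projected 1×1 —
these fusions are the distillation taps.  ASPP applies parallel dilated
3×3 convolutions (1×1 for rate 1, rates `(1, 6, 12, 18)`) on the deepest
fusion; the decoder concatenates a projected low-level fusion with the
upsampled ASPP output, applies two depthwise-separable blocks, and a 1×1
head yields one logit channel per class at half the input resolution,
upsampled (nearest) back.

All convolutions except skip projections and the head are followed by group
normalization (≤ 8 channels per group); without it, float32 training at the
default learning rate is unstable at this width.  Initialization is
He-normal with a seeded generator, so a (config, seed) pair reproduces
parameters bit for bit.  Defaults: `base_width=8`, 2-D, four stages — small
enough to train on one CPU in seconds per epoch.  `base_width=64` with a
7×7 stem reconstructs the full-scale layout as a configuration preset, not
a tested surface.  Only `spatial_dims=2` is implemented; requesting 3 raises
immediately.

The network and trainer run on `podseg._autograd`, a ~400-line reverse-mode
autodiff engine over numpy float32 arrays (im2col convolution, group norm,
nearest upsampling, a weighted masked softmax cross-entropy node, and a
local-POD loss node whose backward is the analytic adjoint of the pooling).
Every operation's gradient is verified against central finite differences in
the test suite.

## Training recipe

SGD with momentum 0.9, initial learning rate 0.0325, poly decay
`lr0·(1 − iter/total)^0.9`, weight decay 0, per-epoch shuffling driven by
the run seed, batch size 4, λ = 0.01.  The reference recipe trains ~30
epochs per step; the desk-scale benchmark uses 5 epochs per step so that a
full two-arm, three-seed comparison completes in a few minutes on one CPU.
Identical seeds and configuration reproduce the loss trajectory exactly,
and `total = pseudo + λ·distill` is asserted at every logged epoch.

## Synthetic phantoms

Each phantom is a randomly deformed, anisotropically scaled set of three
concentric regions on a 64×64 grid (32³ available in 3-D): enhancing tumor
(label 4) innermost, necrotic core ring (label 1), edema ring (label 2).
One shared low-order angular deformation field guarantees ET ⊆ TC ⊆ WT by
construction.  Four modality channels draw per-region mean intensities from
a table chosen so the edema ring is bright in the FLAIR analog and the
enhancing core bright in the T1-CE analog, plus Gaussian noise
(σ = 0.05 against region contrasts of ~0.3–0.7).  Default geometry (whole
radius 16 % of the grid, ±15 % jitter) keeps background above 80 % of
pixels, echoing the heavy class imbalance of real data.  All randomness is
seed-derived; the same seeds reproduce images, masks and NIfTI files byte
for byte (uncompressed `.nii`, fixed headers).

What the phantoms do *not* emulate: MRI physics (bias fields, partial
volume, anatomy), inter-case registration error, and realistic boundary
texture.  Passing benchmarks here demonstrates that the continual-learning
mechanics work as specified — that distillation and pseudo-labels preserve
old-class performance where naive fine-tuning erases it — not that any
particular Dice level transfers to clinical data.

## Numerical and reporting conventions

* Dice `2TP/(FN+FP+2TP)`; two empty masks give 1.0, flagged.  Sensitivity
  and specificity return NaN (flagged) on empty denominators, never a
  silent 0; aggregation over cases skips flagged values and records how
  many were skipped.
* Hausdorff95: surfaces are foreground voxels with a background
  face-neighbor, coordinates scaled by voxel spacing (default 1.0);
  directed nearest-neighbor distances are pooled across both directions and
  the 95th percentile taken (max-of-directions available via
  `pool_directions=False`); percentile 100 is exactly the classical sup-inf
  Hausdorff distance and is verified against a brute-force double loop.
* Z-score standardization uses the population standard deviation over the
  whole volume by default (a nonzero-voxel domain is available for
  zero-filled backgrounds); constant channels are rejected by modality name.
* Cropping centers the window on the foreground bounding-box center
  (integer floor), clips to the volume and zero-pads; augmentation uses
  exact 90° rotations by default (free-angle behind a flag), identical
  transforms for image (linear) and labels (nearest), and can never
  introduce new labels.
* The report tooling compares ablation arms as relative percent improvement
  for overlap metrics and absolute reduction for Hausdorff95, matching how
  such tables are usually discussed.

## Problem sizes

The bundled forgetting benchmark uses 40 training and 10 validation
phantoms at 64×64 with `base_width` 8, 5 epochs per step and three paired
seeds; oracle checks run 100 random instances each.  These sizes were
chosen so the complete suite and the acceptance script each finish within a
few minutes on a single CPU while still separating the training arms
decisively.

## Known limitations

* The step-1 teacher trained for 5 epochs is weak (class-1 Dice ≈ 0.2), so
  pseudo-labels recover edema much better than necrotic core; longer step-1
  training raises both.
* The tiny enhancing region (~1 % of pixels) is at the edge of what the
  desk-scale model learns in 5 epochs; new-class Dice after step 2 is low
  in all arms and is not part of any claim.
* `v` is computed per image and the loss averaged over the batch; per-batch
  pooling would weight images with many candidates differently.
* The 3-D code paths (phantoms, preprocessing, metrics) are exercised in
  tests, but the network itself is 2-D.
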