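# Methods

## Problem and model

`voxsegan` segments BraTS-style multimodal 3D brain MRI (T1, T1gd, T2,
FLAIR) into background, edema (ED), non-enhancing core (NET) and
enhancing tumour (ET) with a conditional adversarial pair:

* **Generator** G: an encoder–decoder over cubic patches of side P
  (P divisible by 16). Four stride-2 convolutional blocks (kernel 4,
  "same" padding, leaky ReLU slope 0.2) double the filters from
  `base_filters` (64 at full scale) to 8×`base_filters` while the side
  shrinks to P/16; four stride-1 residual blocks with dropout 0.2 operate
  at that bottleneck; three stride-2 transposed-convolution blocks (ReLU)
  and a final stride-2 transposed convolution with channel softmax return
  to P³×4. Encoder outputs are concatenated onto the matching decoder
  resolutions (skip connections). Instance normalisation follows every
  convolution except the first encoder block.
* **Discriminator** D: a 3D patch critic on the 8-channel concatenation of
  image and segmentation (one-hot ground truth y, or the generator's
  softmax ŷ — kept soft so gradients flow). Four stride-2 blocks identical
  in configuration to the encoder, then a kernel-4 stride-1 convolution to
  one channel and a sigmoid: a (P/16)³×1 field of realness scores rather
  than a single scalar, so the critic judges local anatomy.

Losses (per batch):

* `GL = L1(D(x, ŷ), 1) + α·GDL(y, ŷ)` with α = 5 by default.
* `DL = L1(D(x, y), 1) + L1(D(x, ŷ), 0)`.
* `L1(·, c)` is the **mean** absolute deviation over the realness field
  (mean, not sum, so loss magnitudes are independent of patch size).
* `GDL` is the pooled generalized dice loss with inverse-square-volume
  class weights `w_c = 1/(V_c + ε)²`, ε = 1e-6. Two numerical choices
  matter: (i) a class absent from the batch (V_c = 0) would receive weight
  1/ε² ≈ 10¹² and swamp every present class through the denominator, so
  empty classes get weight 0 — the convention of standard generalized-dice
  implementations; (ii) the outer ratio carries no ε (its denominator is
  strictly positive for any valid one-hot truth), which makes
  GDL(y, y) = 0 hold exactly, not merely to O(ε). A `uniform` weighting is
  available for ablation; note that in the pooled formula uniform weights
  are dominated by the background class and give almost no tumour signal.

Training alternates one discriminator update (generator output treated as
constant) and one generator update (discriminator frozen; its weight
gradients from the pass-through are discarded) per batch, with Adam
(β₁ = 0.5, β₂ = 0.999). Prediction tiles a volume with overlapping
patches, averages class probabilities in overlaps, and takes the
per-voxel argmax.

## Why the decoder has skip connections

An early skip-free variant of the generator — the same block sequence
without encoder→decoder concatenation — reproducibly failed to learn the
segmentation at desk scale: the only route from input to output is the
(P/16)³ bottleneck, and under the pooled dice loss the cheapest descent
direction is to suppress rare-class probabilities globally rather than to
place a ~10²-voxel enhancing core precisely. With skips the same schedule
segments held-out phantoms with whole-tumour DSC ≳ 0.9. Skip
concatenation changes no stage shape (bottleneck and output are
identical) and is standard in the volume-to-volume GAN family this design
follows; it can be disabled with `GeneratorSpec(skip_connections=False)`
for the ablation.

## Phantom simulator

The simulator emulates the *structure* of a multimodal glioma case, not
its anatomy or MR physics. Per case: a brain ellipsoid (semi-axes
`brain_radius_frac`·G/2 scaled by fixed anisotropy (1.0, 0.85, 0.75)) on
a G³ grid (default 64³); an edema ellipsoid with radius drawn from
`tumour_radius_range` (default 8–14 voxels) and per-axis eccentricity in
[0.75, 1], placed uniformly so its bounding sphere stays inside the
brain; concentric NET and ET cores at 0.65 and 0.35 of the edema radius.
Each modality channel is a per-(modality, class) mean-intensity table plus
i.i.d. Gaussian noise (σ = 0.08 in table units). The default table makes
edema FLAIR/T2-bright and the active rim T1gd-bright with class contrasts
of 2–7 σ, so classes are separable but overlap under noise — the regime
that motivates dice-weighted training. Everything is a pure function of
(seed, case index) via seeded generators.

What the phantoms do **not** model: anatomy (tissue interfaces, cortical
folding), bias fields, motion artefacts, partial-volume mixing,
non-ellipsoidal or infiltrative tumour geometry, inter-case intensity
distribution shift. Passing the desk-scale tests therefore demonstrates
that the pipeline, losses and optimisation behave as designed on a
separable-but-noisy 4-class nested task; it does not certify performance
on clinical BraTS data.

## Preprocessing and patch sampling

* Intensity normalisation: per-channel z-score over nonzero (brain)
  voxels, population std; constant channels map to zeros. Min–max
  scaling to [0, 1] is a config option. (Whether normalisation should use
  brain voxels or the whole volume is a free choice; the z-score-over-
  brain-voxels convention is the default and documented rather than
  guessed further.)
* Tiling: `extract_patches` places corners at 0, S, 2S, … plus a final
  corner flush with each axis end, so every voxel is covered; used for
  prediction and coverage-style training sets.
* Training sets additionally use `sample_tumour_patches`: crops centred
  on the tumour centroid with ±4-voxel jitter (foreground oversampling),
  mixed with tiled background-heavy crops, so the network sees both
  tumour-centred and tumour-free patches.
* Augmentation: independent axis flips (p = 0.5 each) and a uniformly
  drawn axial 90° rotation, applied identically to image and one-hot
  labels. These are voxel permutations: no interpolation, class counts
  preserved.
* Coordinates are 0-based (x, y, z); public arrays are channels-last.

## Scale choices

The full-scale configuration (128³ patches, base 64, batch 4, 100 epochs)
is the document-of-record setting but needs GPU-class hardware. The
package's canonical desk-scale surrogate (`voxsegan.presets`) is:
64³ phantoms, 7 cases (5 train / 2 held out), 20 training patches of 32³
(3 tumour-centred + 1 tiled per training case), base 8 filters, 30
epochs, batch 4, prediction stride 16. This runs in a few minutes on one
CPU. Its learning rate is 2e-3: the 2e-4 default is matched to full-scale
schedules with thousands of optimiser steps, and in the surrogate's ~150
steps it measurably fails to move the model; the larger step size is a
property of the short schedule, not of the model. Both rates are plain
config fields.

## Numerical and design notes

* All layer backward passes are verified against central finite
  differences (float64) in the test suite, and transposed convolution is
  implemented as the exact adjoint of the strided convolution (checked by
  the inner-product identity).
* "Same" padding for kernel 4 is asymmetric — (1, 1) at stride 2,
  (1, 2) at stride 1 — matching the usual even-kernel convention; an
  even kernel therefore shifts flip-equivariance by one voxel, which the
  tests account for.
* Weight initialisation: zero-mean Gaussian, std 0.02, from a seeded
  generator; instance-norm affine parameters start at (1, 0).
* Dice/PSNR/SSIM conventions: whole-tumour DSC binarises labels > 0 with
  the both-empty-scores-1 convention; PSNR and SSIM compare label maps
  rescaled to [0, 1] (dynamic range 1), SSIM with a uniform 7-wide window,
  C1 = (0.01L)², C2 = (0.03L)², unbiased covariance — identical to the
  common reference implementation, against which it is tested to 1e-6.
  Per-image PSNR/SSIM of external studies depend on their (unpublished)
  reference signals; only cohort-mean aggregation of published per-image
  rows is reproducible, which is what the reporting path implements.
* Voxel accuracy (fraction of voxels with correct argmax class) is logged
  alongside DSC as a secondary, imbalance-insensitive diagnostic; this is
  one concrete interpretation of "accuracy" for a segmentation GAN.
* Determinism: phantom cohorts are pure functions of (seed, case index);
  training is a pure function of (networks, dataset order, seed); numpy
  execution is single-threaded deterministic, so identical runs are
  bit-identical.

## Known limitations

* CPU numpy execution: full-scale (128³, base 64) training is out of
  reach; the engine is intended for desk-scale experiments and as a
  reference implementation.
* No Hausdorff distance or sensitivity/specificity reporting; no 2D
  variants, cascades, or alternative adversarial losses (hinge,
  Wasserstein, cross-entropy).
* The phantom cohort is not calibrated to real glioma size/shape
  statistics; defaults were chosen once for plausibility and class
  imbalance, not fitted to any dataset.
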