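# Methods

## The problem

Ultrasound images carry multiplicative speckle: granular interference whose
local strength scales with tissue brightness, obscuring lesion boundaries
and fine anatomy. `mkdespeckle` implements a teacher–student despeckling
pipeline: a U-Net-style teacher is pretrained on (noisy, clean) patch
pairs, then a lightweight uniform-block student is distilled from it with a
composite objective in which the evaluation metrics themselves (PSNR, SSIM)
steer the optimization.

## Noise model

The simulator draws

    I_n(x, y) = I(x, y) + I(x, y)^γ · µ(x, y),        µ ~ N(0, σ)

with γ = 1 by default (fully multiplicative; γ = 0 degenerates to additive
noise) and σ interpreted as the **variance** of the Gaussian field.  Because
sources in this area are inconsistent about whether "σ" denotes a variance
or a standard deviation, `SpeckleParams.sigma_semantics` makes the
interpretation explicit and every dataset records it in its provenance.
The noisy image is *not* clipped to [0, 1] by default: clipping would bias
the stated moments (for a constant image of value c, Var(I_n − I) = c²σ);
clipping is available as an explicit option for 8-bit export.

## Phantoms

The generator emulates what matters for this evaluation, not ultrasound
physics: a piecewise-smooth background (gentle ramp plus band-limited
texture), elliptical bright/dark lesions with sharp boundaries, and one
straight-edged bright band so that edge-preservation metrics always have
reference edges.  A rectangle in the upper-left corner is kept free of
structures and serves as the default homogeneous region for ENL.  The
phantoms have no point-spread function, no log-compression, no attenuation
or shadowing; passing tests on phantoms demonstrates that the pipeline and
its contracts work, not that clinical image quality is reached.

## Augmentation, patching, splits

Augmentation is a deterministic 4-variant enumeration (original, 90°
rotation, horizontal flip, vertical flip) so corpus counts are exactly
reproducible: 780 images become 3 120, and 64×64 patching at stride 64 of
256×256 images yields 49 920 patches.  Patches are half-open raster-order
windows; incomplete border windows are discarded.  Splits are made at the
source-image level before augmentation, and only the training partition is
augmented, so no image contributes patches to two partitions.

## Networks

*Teacher*: conv(3×3, stride 1)/batch-norm/LeakyReLU(0.2) blocks; four
2×2 max-pool stages with filter counts 64→128→256→512; a 1024-filter
bottleneck at 4×4 spatial size (for 64×64 input); a mirrored decoder using
nearest-neighbour 2× upsampling followed by convolution (avoids
checkerboard artifacts); skip connections concatenate encoder features into
the matching decoder stage; a linear 3×3 head maps back to the input
channels.  *Student*: a stem block, 16 identically-shaped 64-filter blocks
at constant spatial size — no pooling, no bottleneck — and a linear head.
Kernel sizes, the filter schedule, the LeakyReLU slope and skip fusion by
concatenation are this package's choices where the architecture family
leaves them open; all are configurable in the specs.

Both networks offer a global residual head (`output = input + correction`)
whose final convolution is zero-initialized, so an untrained network is
exactly the identity.  For denoising this is the natural origin — early
gradients learn the noise instead of rediscovering the image — and it keeps
the PSNR-normalized loss well-behaved from the first batch (see below).
The option is off by default and on in the desk-scale profile.

`width_multiplier` scales every filter count; 0.125 turns the ~18.8 M
parameter teacher into a ~295 k one with identical topology.

## The composite objective

The student minimizes

    (MSE + α·KD + β·(1 − SSIM) + γ·L1) / PSNR

with α = 0.3, β = 1, γ = 1, temperature T = 0.8 and ε = 1e-10.  Notes on
the design:

* **SSIM sign.**  The structural term enters as the dissimilarity 1 − SSIM,
  so minimizing the loss raises SSIM.  A `plus_ssim` switch adds +SSIM
  instead; it exists for ablation only, since minimizing +SSIM drives
  structural similarity down.
* **KD term.**  Each patch's output is flattened to a pixel-logit vector,
  softmaxed at temperature T on both the (frozen, detached) teacher side
  and the student side, and scored with KL(teacher ∥ student) in nats,
  ε added inside both logarithms.  Averaged over the batch.
* **PSNR divisor.**  The batch PSNR (standard convention, peak 1) is a
  *detached* scale factor — no gradient flows through it — floored at ε.
  When the output is poor the effective loss inflates, and it relaxes as
  quality rises.  When the numerator is exactly zero the total is zero, so
  the MSE = 0 PSNR sentinel (0 dB) never produces 0/0.  Note the floor
  also means a batch with MSE > peak² (negative PSNR) would explode the
  loss scale; starting residual networks at the identity keeps the divisor
  in its sane regime from the first step.  Adam's per-coordinate
  normalization makes training robust to the divisor's scale either way.
* **Teacher loss.**  The same objective with the distillation term removed
  (α treated as 0).

## PSNR convention

The package computes PSNR as `10·log10(peak²/MSE)` with peak = the span of
the declared range, returning a configurable sentinel (default 0 dB) when
MSE = 0.  A `peak_over_mse` convention computing `10·log10(peak/MSE)` is
available for comparison with sources that print that form; on [0, 1] data
with RMSE 0.004 the standard convention gives ≈ 47.96 dB, consistent with
the ~48–49 dB figures reported for strong denoisers in this literature.

## Metrics

* **SSIM**: Gaussian-weighted 11×11 window (σ = 1.5), c1 = (0.01·L)²,
  c2 = (0.03·L)², weighted moments without sample-size correction, valid
  windows only, per-channel mean.  Verified against
  `skimage.metrics.structural_similarity` in the same convention.
* **ENL**: mean²/variance (population convention) over an explicit ROI; a
  zero-variance ROI raises `DegenerateRegionError` rather than returning
  infinity.  The CLI defaults to the phantom generator's reserved
  background rectangle.
* **FOM**: Pratt's figure of merit with α = 1/9; Canny edges (σ = 1.5,
  thresholds 0.10/0.20) detected identically on both images; distances via
  an exact Euclidean distance transform.  The specific edge-detector
  settings are this package's (recorded in `FOMParams`), so absolute FOM
  values are comparable only within a configuration.

## Training procedure

Adam (β1 = 0.9, β2 = 0.999), default lr 5e-4, batch 32, up to 100 epochs,
validation each epoch, best-validation-PSNR weights restored at the end.
The learning rate is halved (floor 1e-6) when validation PSNR has not
improved for 5 consecutive epochs; the ablation harness's fixed-schedule
arm instead multiplies the rate by 0.96 every 10 epochs.  Runs are
single-threaded and fully seeded: identical configurations reproduce
bit-identical logs.  The teacher is trained to convergence first and is
strictly frozen during distillation (asserted in tests, including its
batch-norm running statistics).

## Desk-scale profile

`training.desk_profile()` defines the one-CPU experiment used by the test
suite and the acceptance script: 13 single-channel 192×192 phantoms (10
train / 2 val / 1 test), one noise level (variance 0.09), 360 training
patches; teacher at width multiplier 0.125 for 8 epochs; a short wide
student (4 blocks × 16 filters, residual head) distilled for 20 epochs;
Adam at 5e-3 with batches of 16.  The student keeps the uniform-block
topology but trades depth for width relative to the full-scale 16×64
design: at a few hundred optimizer steps a shallower stack trains to a
usefully higher PSNR in the same wall-clock budget.  The smaller batches and larger step size compensate for
the small corpus — a few hundred optimizer steps have to do the work that
the full-scale recipe spreads over ~100 000.  At this scale the distilled
student reliably clears the noisy input by far more than 3 dB and edges
past the 5×5 median baseline; it does not approach the ~39 dB that
GPU-scale training on a clinical corpus reports at this noise level, and
is not meant to.

## Numerical engine

No deep-learning framework is part of the dependency set; the networks run
on an in-package reverse-mode autodiff engine over numpy (`mkdespeckle.nn`)
with exactly the ops the models need.  Convolution is im2col + BLAS matmul
in channels-last layout; its backward pass uses a shift-accumulate form
(one small matmul per kernel offset) chosen because it keeps every gather
row-contiguous.  Parameters are float32; loss and metric computations on
plain numpy inputs run in float64, which is what the 1e-9–1e-12 agreement
tolerances in the test suite rely on.  Gradients of every structured op are
verified against central finite differences.

## Known limitations

* Phantoms are geometric stand-ins; no claim of clinical realism.
* The desk-scale student/teacher PSNRs are not comparable to full-scale
  GPU-trained results and the package does not attempt to reproduce them.
* ENL and FOM absolute values depend on ROI and edge-detector settings,
  which published tables typically leave unstated; they are reported, not
  matched against external numbers.
* The engine is CPU-only and sized for 64×64 patches and desk-scale
  networks; the full-width teacher runs but trains slowly.
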