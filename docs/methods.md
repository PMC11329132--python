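# Methods

## Problem and model

Standard CT acquisition trades through-plane resolution for dose: a
3 mm-thick slice averages three times the tissue of a 1 mm slice and is
acquired at three times the scanning interval.  `ctthinslice`
implements a conditional-GAN approach that *simultaneously* reduces
slice thickness and interpolates adjacent slices: from each thick slice
x it generates the five thin slices spanning the thick slice's extent
and its immediate neighbourhood — two before (2P), one before (1P), the
corresponding centre slice (C), one after (1N), two after (2N).  One
generator is trained per position; the five are trained independently,
with no weight sharing.

Two training-target constructions are compared:

* **Method 1 (raw targets).**  The generator maps the thick slice
  (scaled to [-1, 1]) directly to the thin slice on the same scale:
  `y_hat = G_pos(x')`, rescaled to stored values.
* **Method 2 (residual / difference targets).**  The generator predicts
  the *difference image* between thin and thick on the [0, 1] scale:
  the target is `unit(y) - unit(x)` (which lies in [-1, 1] by
  construction), and at inference the prediction is added back to the
  [0, 1]-scaled input, clipped, and rescaled.  Residual learning starts
  from "output = input" semantics and only has to model what *changes*
  between thick and thin.

The architecture and objective follow the pix2pix image-to-image
translation recipe: a U-Net generator (encoder-decoder with skip
connections between mirrored levels, tanh output so generated images
never leave [-1, 1]) and a conditional PatchGAN discriminator that
scores the channel-concatenated (input, candidate) pair as a 2D grid of
patch logits.  The generator loss is the non-saturating adversarial
binary cross-entropy plus `lambda * L1(y, G(x))` with `lambda = 100`;
the discriminator loss is the mean BCE over real/fake patch grids
(labels 1/0).  Optimisation is Adam with learning rate 2e-4 and
`beta1 = 0.5`, batch size 1 — the published pix2pix defaults.

The networks are implemented directly in NumPy with hand-written
backpropagation (`ctthinslice.nn`): im2col-based convolutions, nearest
upsample + 3x3 convolution in the decoder (checkerboard-free, with an
exact adjoint), instance normalisation (identical to batch
normalisation at batch size 1 in train mode, and deterministic), and
bias-corrected Adam.  Every layer's gradient is validated against
float64 central differences in the test suite.  Deliberate deviations
from the original torch recipe: transposed convolutions are replaced by
upsample+conv, and decoder dropout is omitted so that desk-scale runs
are bit-reproducible.

## Scaling conventions

Stored values are 12-bit integers in [0, 4095] (HU = stored + rescale
intercept, typically -1024).  Two real-valued scales are used:

* signed: `x' = x / 2047.5 - 1`, so 0 -> -1 and 4095 -> +1 exactly
  (network input/output range);
* unit: `x / 4095` (residual arithmetic).

`unit = (signed + 1) / 2` holds exactly, and denormalisation
(`round(clip(...))`, halves away from zero) is the exact inverse on all
4096 stored values.  The exact affine maps are a declared design
choice; mapping range endpoints to scale endpoints is the least
surprising completion.

## Slice mapping and assembly

For thickness ratio k (odd, default 3), thick slice j's corresponding
thin index is `C = k*j + (k-1)/2` — the geometric centre of the k thin
slices it averages.  The mapping table assigns 2P..2N to C-2..C+2;
entries outside the thin volume (2P of the first thick slice, 1N/2N of
the last) are *absent* and skipped, never padded — fabricating boundary
targets would misstate provenance.  Consecutive rows overlap at exactly
two thin indices; at inference, overlapping predictions are reconciled
by an unweighted mean (default) or by preferring the positionally
nearest contributor (`overlap="nearest"`).  The mean is symmetric and
variance-reducing; the blending rule is a package decision — per-slice
generation alone does not determine how overlapping predictions from
adjacent thick slices are reconciled.  Uncovered boundary thin indices
are omitted and the output records its index offset.

Only odd integer thickness ratios are supported; non-integer ratios
(e.g. a 3 mm : 0.7 mm interval pairing) have no centre-aligned mapping
and are rejected with a clear error rather than guessed at.

## Phantom generator

Clinical paired 1 mm/3 mm volumes are not distributable, so the package
ships a procedural wrist-like phantom: an air background, a soft-tissue
ellipse, 1-2 closed cortical shells (bright annuli, ~2800 stored
values) with textured marrow interiors, an optional one-voxel oblique
fracture plane at soft-tissue intensity, and additive Gaussian
acquisition noise, clipped and rounded to stored values.  Shell edges
are rendered with a ~1-voxel linear ramp so sub-voxel through-plane
motion produces graded partial-volume intensity changes, as in real CT.

Through-plane structure is what the method must learn, so shell centres
drift at a fixed (0.3, 0.2) voxels/slice and radii grow at 0.25
voxels/slice — rates shared across cases of a suite (learnable), while
shell placement, sizes, texture and noise are case-random.  Default
study conditions: 30 thin slices of 64x64, k = 3, texture amplitude 150
stored values with correlation length 2 voxels, noise sigma 5 (a
low-noise regime: the noise floor alone sits near 58 dB PSNR).

Thick slices are synthesised as the unweighted mean of k consecutive
thin slices at stride k — the standard partial-volume model for
virtually generated thick images.  Rounding is half-away-from-zero for
platform stability.

What the phantom does *not* emulate: scanner physics (beam hardening,
helical artifacts), anatomically realistic wrist geometry, HU
calibration, gantry-rotation-direction effects.  Passing tests
demonstrate that the pipeline is internally correct and that learning
occurs on structured volumes; they do not certify clinical image
quality.

## Evaluation

PSNR, MSE and SSIM are computed on unit-scaled images with peak 1, so
MSE 1e-4 is exactly 40 dB (and e.g. MSE 1.23e-5 is ~49 dB).  SSIM uses
the original windowed form: 11x11 Gaussian window
(sigma 1.5), C1 = (0.01 L)^2, C2 = (0.03 L)^2, L = 1, weighted local
statistics without sample-covariance correction, averaged over fully
valid window positions.  Infinite PSNR (identical slices) propagates as
+inf in per-slice records and is excluded from means with a logged
count — capping would fabricate numbers.  Per-case aggregation reports
both the slice-pooled mean and the mean of per-case means.

Method comparison counts per-slice winners: the PSNR/MSE family is
counted once (lower MSE wins; PSNR is strictly decreasing in MSE so the
orderings coincide — asserted as a property), SSIM separately; exact
ties are tallied in their own column rather than awarded.  Cohen's
kappa for the two-rater grading workflow is implemented from the
contingency definition `(p_o - p_e) / (1 - p_e)`, with the degenerate
single-category case defined as 1 for perfect agreement and an error
otherwise.

## Desk-scale training profile and what it shows

The default profile trains each position model for 10 epochs, batch
size 1, generator depth 6 / base width 32, discriminator with 3 strided
blocks / base width 32, on 64x64 phantoms.  These sizes were chosen so
a full two-method leave-one-case-out fold runs in minutes on one CPU;
full-resolution, long-schedule training is configuration, not code.

At this profile the models are demonstrably *underfit*: training-set
reproduction and held-out scores are nearly equal, and
`scripts/acceptance.py` shows both methods still score below the
copy-thick-input baseline on the held-out case.  The per-position
breakdown explains why: after ~300 Adam steps per model the generators
already beat a plain copy at the hard +-2-slice offsets, but cannot yet
reproduce fine in-plane detail at the centre position, where copying
the input is nearly optimal on a 10-slice-thick average.  Closing that
gap requires the longer schedules the original recipe uses (hundreds of
epochs), which is outside the desk profile by design.  The pipeline's
correctness is therefore established separately, by closure: when the
five generators are stubbed with their ground-truth targets, volume
enhancement reproduces the thin phantom exactly (within 1 stored unit
of rounding), for both methods.

## Numerical and degenerate-input choices

* All scaling arithmetic in float64; network arithmetic in float32;
  stored values uint16.
* Rounding is always half-away-from-zero (explicit, platform-stable).
* Instance norm passes 1x1 spatial extents through unchanged (the U-Net
  bottleneck is degenerate there).
* Method 2 clips on the [0, 1] scale *before* rescaling: adding a
  [-1, 1] residual to a [0, 1] image can leave the range, and
  clip-then-round is the only safe reading of the stored-value
  contract.
* Even thickness ratios are rejected (no centre slice); empty example
  lists, mixed positions/methods in one training call, mixed DICOM
  geometry, and missing spacing metadata are errors, never guesses.
* Determinism: one seed fans out to stage-specific seeds via crc32
  hashing; fixed seed + config reproduces bit-identical phantoms,
  bundles, and reports on one platform.

## Known limitations

* No in-plane super-resolution, non-integer thickness ratios, 3D
  convolutions, or alternative generator families.
* The phantom family's through-plane dynamics are simple rigid
  drift/growth; real anatomy moves less predictably.
* The desk-scale profile demonstrates learning mechanics, not clinical
  image quality; see above.
* DICOM support covers the geometry + pixel-module subset needed for
  round-tripping axial series, not full conformance.
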