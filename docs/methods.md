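# Methods

`endostitch` implements a two-stage unsupervised stitcher for overlapping
endoscope frames: a multiscale deep homography network aligns an image pair,
and a mask-constrained two-branch fusion network blends the aligned pair into
one mosaic.  Neither stage uses labels; both are trained from photometric
consistency alone.  This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Alignment model

Two normalised images (values in [0, 1]) are stacked along channels into an
`[H, W, 2C]` tensor.  A shared-weight convolutional extractor (eight 3×3
convolutions with leaky-ReLU, stride-2 downsampling, 16/24/32 channels)
processes each half independently and produces feature pyramids at 1/2, 1/4
and 1/8 of the input resolution.  Going coarse to fine, unit-normalised
features are correlated inside a local window (radius 4 at 1/8 resolution,
2 elsewhere) and a regression head turns the correlation volume into a
residual update of the **4-point parameterisation**: the pixel displacements
of the four target-image corners.  The running displacement is converted to
the 3×3 homography by a **tensor DLT** — the standard direct linear transform
solved as a batched 8×8 linear system in float64, with an analytic adjoint so
corner offsets receive gradients.  The homography maps target coordinates
into the reference frame; finer-level target features are pre-warped by the
running estimate, so each level only regresses a residual.

Each regression head sums two paths:

* a learned path — two stride-2 convolutions, adaptive 4×4 average pooling
  and two fully connected layers, final layer zero-initialised (an untrained
  network therefore predicts exactly zero offsets, i.e. the identity
  homography);
* a fixed patch-matching path — zero-mean 3×3 patches of the pooled
  grayscale images, unit-normalised and correlated in the same window; a
  soft-argmax gives the expected displacement per position, averaged over
  the four spatial quadrants and assigned to the matching corners through a
  learnable scalar gate (initialised at zero).

The second path exists because discovering the correlation-to-displacement
mapping from photometric gradients alone takes orders of magnitude more
optimisation steps than a desk-scale run allows; with the decoder built in,
the gate (a single scalar per level) aligns the estimate within a few dozen
Adam steps and also learns to compensate the systematic under-estimation of
a soft-argmax, after which the learned path refines.  Running offsets are
hard-clamped to ±size/4 with a straight-through gradient: clamping keeps the
DLT well conditioned, and passing the gradient unchanged means an estimate
pushed against the bound can always be pulled back (a saturating clamp
permanently freezes training once exceeded — observed, not hypothetical).

**Loss.**  The photometric ablation loss is the mean absolute difference
between the warped target and the reference multiplied by the warped
footprint mask, normalised by mask area — evaluated at each pyramid scale
with the homography implied by the running offsets at that scale (weights
1/2/4 fine→coarse; the coarse term dominates early training when only the
widest window sees the true motion), and **in both warp directions**
(target→reference through H, reference→target through H⁻¹).  The
bidirectional form is essential: a one-sided, area-normalised ablation loss
has a degenerate optimum in which the network shrinks the warped footprint
onto featureless regions; the reverse direction turns that shrinkage into a
mismatched zoom and removes the degeneracy.

## Double-H warping

The aligned pair is placed on a shared black canvas that tightly bounds the
reference rectangle and the projected target quadrilateral.  The reference
is moved by an integer translation only (never resampled); the target is
backward-warped by the translation composed with the homography, with
bilinear sampling and zero padding.  Footprint masks are the warped all-ones
image thresholded at 0.999, excluding partially covered border pixels from
all losses.  Warping is deterministic and differentiable.

## Fusion model

The fusion network consumes the 8-channel canvas stack (both warped RGB
images plus both masks).  The *pixelisation deformation* branch (three 3×3
convolutions each followed by 2×2 average pooling, then three stride-2
transposed convolutions and a sigmoid output head; widths 16/24/32) learns
the blending rules at a working resolution capped at 256 px per side.  The
*refinement* branch (three convolutions, then eight combination blocks —
each a residual pair of 3×3 convolutions — width 8, final layer
zero-initialised) adds a full-resolution correction, so the fused mosaic is
`clip(upsample(low_res) + residual, 0, 1)` and equals the deformation output
at initialisation.

Supervision comes from masks derived from the canvas:

* **content masks** — each image's footprint minus the overlap; an L1 term
  ties the fused mosaic to the original pixels there;
* a **seam mask** — the overlap region with edges smoothed by a 5-px
  Gaussian; a gradient-consistency term penalises differences between the
  fused image's finite-difference gradients and each source's, suppressing
  visible seams;
* a low-weight **overlap term** — L1 between the fused overlap and the mean
  of the two aligned sources.  Content and seam terms alone leave the
  absolute intensity of the overlap unconstrained (gradients fix texture but
  not the DC level, and for a fully overlapping pair the content masks are
  empty), so this term anchors it.  Default weights are content 1.0, seam
  0.5, overlap 0.25, applied at both branch resolutions.

## Synthetic data

Real cystoscopy videos are not publicly deposited, so training and
evaluation use generated frames that emulate their salient properties:
band-limited reddish random fields with dark vessel-like random-walk curves
(mucosa texture), an optional circular vignette (radius 0.95 of the
half-width by default), brightness jitter (±10 %) and Gaussian blur
(σ ∈ [0, 1.5] px).  A pair is rendered from one oversized texture — the
reference as a central crop, the target sampled through the ground-truth
homography — so the pair is exactly consistent with `h_true` up to
photometrics and interpolation.  Corner offsets are rejection-sampled
(translation proposals biased per overlap grade, verified against the exact
polygon-clipped overlap rate, capped at 1000 attempts) to hit the three
overlap grades: small < 40 %, medium 40–80 %, large > 80 %.  Grade shares
round down per grade with the remainder assigned to the last-listed grade.
Everything derives from one dataset seed and regenerates bit-identically.

What the generator does **not** emulate: specular highlights, floating
debris, fluid turbidity, rolling-shutter or lens-distortion effects, and
real tissue deformation (the true warp is exactly projective).  Passing
tests therefore demonstrate that the machinery recovers known geometry and
smooths seams under controlled corruption — not clinical-grade performance
on patient video.

## Training schedule

The full recipe follows a two-phase schedule: 120 epochs of pre-training on
128×128 pairs, then 80 epochs of fine-tuning at 512×512 (the network is
fully convolutional; adaptive pooling makes the heads resolution-agnostic),
with Adam at an initial learning rate of 1e-4 decayed exponentially
(×0.97 per epoch by default; the decay factor is a free parameter).  Batch
sizes default to 8 at 128 px.  All randomness (weights, shuffling, data)
derives from one config seed, and runs are bit-reproducible single-threaded.

The *scaled-down* experiments used by the test suite and the acceptance
script train on 256 noiseless pairs (corner perturbations ≤ 16 px, no
vignette) for 1,500 steps at batch 4 and learning rate 3e-4 — a rate chosen
for short runs, where 1e-4 barely leaves initialisation — and train the
fusion branches for 1,000 single-canvas steps at 1e-3.  Problem sizes
(256/64 alignment pairs, 32 fusion canvases, 50 seam-evaluation pairs,
300 outcome-agreement pairs, 90 robustness pairs) are chosen so the whole
suite runs on one CPU core in well under an hour.

## Outcome classification

Stitch outcomes are labelled *error*, *failure* or *success*.  Errors are
geometric: ill-conditioned homography (condition number of the
similarity-normalised matrix > 1e4 — raw pixel-coordinate condition numbers
are dominated by translation), non-convex or orientation-reversing projected
quadrilateral, area ratio outside [1/4, 4], empty overlap, or a degenerate
(constant) input image.  Failures are misalignments.  Because no ground
truth exists at deployment, misalignment is *measured*: a staged
block-matching registration (zero-mean 3×3 patch ZNCC with sub-pixel
parabolic refinement, IRLS affine fits with a final projective fit,
coarse-to-fine at 1/4 → 1/2 → full resolution) estimates the residual
transform between the two aligned images and extrapolates it to the four
reference-frame corners — the same summary the 5-px ground-truth rule
applies.  A stitch fails when the extrapolated residual exceeds 4.5 px or
the final-stage inlier fraction falls below 0.40; both defaults were
calibrated once against ground-truth labels on 350 synthetic validation
pairs (seeds disjoint from every benchmark seed) and then frozen.  The
projective final fit matters: large-overlap pairs can be well aligned over
most of the overlap while a perspective residual grows past 5 px at the
corners, which an affine fit systematically misses.

## Numerical choices

* DLT systems are solved in float64; network arithmetic is float32.
* Bilinear sampling uses zero padding for warps (masks account for
  coverage) and border padding for constant resampling grids.
* The overlap rate is computed by exact convex-polygon clipping of the
  projected square `[0, size]²` (projections stay convex over the sampled
  perturbation range), so a pure translation by `t` gives exactly
  `(size − t)/size`.
* Corner order is top-left, top-right, bottom-right, bottom-left
  everywhere; coordinates are 0-based pixel centres, x along columns.
* Adam uses β = (0.9, 0.999), ε = 1e-8; gradients are not clipped.
* SSIM follows the standard Gaussian-weighted definition (11-px window,
  σ = 1.5, K1 = 0.01, K2 = 0.03, dynamic range 1) on the luminance channel;
  TV is the anisotropic mean absolute neighbour difference, so values are
  comparable across canvas sizes.

## Known limitations

* The backbone and branch widths (16/24/32 extractor, width-8 refinement)
  are sized for single-core CPU training; they are config, not substance,
  but results at these widths should not be read as the ceiling of the
  architecture.
* The patch-matching decoder assumes locally translational motion within
  each correlation window; extreme perspective inside a window defeats it.
* The outcome proxy observes only the overlap; its corner extrapolation is
  exact for projective residuals but cannot see non-projective error.
* At very low overlap (< ~15 %) the registration self-check runs out of
  textured area and the classifier falls back to labelling by coherence,
  which is conservative (biased toward *failure*).
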