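# Methods

`sctkit` implements supervised CBCT-to-synthetic-CT translation for 2-D
axial slices, with a companion registration network that absorbs residual
anatomical misalignment between training pairs, and a phantom generator
that produces fully characterized paired data so every component can be
exercised and scored at desk scale on one CPU.

## Problem setting

On-treatment cone-beam CT (CBCT) carries heavy scatter-induced artifacts —
cupping and shading bias fields, streaks, noise, and miscalibrated HU — that
limit its use for adaptive radiotherapy. Supervised translation to a
CT-like image needs paired (CBCT, planning CT) slices, but clinical pairs
are produced by deformable registration and retain local anatomical
mismatch. Training a synthesizer with a pixel-wise loss against such
targets penalizes the network for being anatomically *right* wherever the
target is wrong. The framework therefore separates the two jobs:

* a **synthesizer** maps the normalized CBCT slice to a synthetic CT (sCT),
  staying in the CBCT's geometry;
* a **registration network** predicts a dense displacement field (DVF)
  between the sCT and the (possibly misaligned) target, and the warped sCT
  (rsCT) — not the sCT itself — is compared to the target by the pixel-wise
  losses. Both networks are trained jointly; gradients flow through the
  differentiable warp into both.

At inference only the synthesizer is used: the registration network is a
training-time device for absorbing target misalignment.

## Data model and preprocessing

Slices are held as HU-valued arrays with pixel spacing (`HUImage`).
Intensities are clipped to the window [-1000, 2200] HU and mapped linearly
onto [-1, 1] (`NormalizedImage` keeps the window so the mapping inverts
exactly; containers store float64 so clip→normalize→denormalize is the
identity to well below 1e-6 HU, while the networks compute in float32).
Training draws one random square patch per slice (identical window for
every image of a pair, reflect-padding inputs smaller than the patch) and
applies flips and 90-degree-multiple rotations with probability 0.3 each.
Rotations are restricted to 90-degree multiples so that displacement fields
re-orient exactly (flip: mirror + negate the mirrored component; CCW
rotation: (u, v) -> (v, -u)) without interpolation. Readers cover DICOM
series (rescale slope/intercept applied), NIfTI volumes (decomposed
slice-wise; the framework is 2-D) and NPZ fixtures.

## Synthesizer

A U-Net whose bottleneck is a stack of transformer blocks operating on
channels rather than pixels:

* a 1x1 stem produces base features (reference width 32);
* each encoder level applies a 3x3 convolution and a stride-2 downsampling
  convolution, doubling channels (capped at 8x base);
* the bottleneck stacks `num_dtb` blocks (reference 9), each being
  pre-norm residual **MDTA** followed by **MSFN**;
* the decoder mirrors the encoder with bilinear upsampling + convolution
  and skip-connection fusion (bilinear-then-conv avoids checkerboard
  artifacts of transposed convolutions);
* a 1x1 head predicts a correction that is added to the input, and the sum
  is clamped to [-1, 1], so the network starts near the identity mapping
  and the output stays in the intensity domain. The head is initialized at
  1% scale — small enough for a near-identity start, non-zero so gradient
  reaches every upstream parameter from the first step. A tanh bound
  composed with the residual was tried first and rejected: it saturates
  over the air background, which is exactly where the CBCT's global HU
  offset must be corrected, and at desk scale it made 20-epoch convergence
  depend on the seed; the clamp keeps full gradient flow inside the
  domain.

**MDTA** (multihead depthwise-convolution transposed attention) produces
Q, K, V with a pointwise convolution followed by a 3x3 depthwise
convolution, then computes attention *across channels*: per head,
softmax(Q K^T / lambda) V where the attention matrix is (C/h) x (C/h),
independent of image size — cost is linear in pixels. lambda is one
learnable temperature per head, initialized to sqrt(C/h). **MSFN**
layer-normalizes, expands channels by a factor (default 2) with a 1x1
convolution, and runs two successive multiscale rounds, each splitting the
channels into a 3x3 and a 5x5 depthwise branch with GELU gating before
re-concatenation, then projects back to the input width.

Channel counts per level, head count, MSFN expansion, and the residual
pre-norm arrangement are exposed in `SynthesizerConfig`; the defaults are
declared choices where the architecture family leaves them open.

## Registration network and warping

The registration network is an encoder-decoder over the 2-channel stack
(sCT, target): a 3x3 stem, `len(down_filters)-1` stride-2 downsampling
convolutions (reference: seven stages with filters 32, 64, 64, 64, 64, 64,
64, 64), residual blocks at the bottleneck (reference: three), and a
mirrored upsampling path with skip connections. The 2-channel head is
zero-initialized so training starts from the identity transform. Inputs not
divisible by 2^stages are reflect-padded and cropped back.

Warping is backward: out(p) = image(p + d(p)), bilinear, border-replicated,
differentiable in both arguments (gradients with respect to the field use
the interpolated image differences). The DVF is in pixels, component 0
horizontal (columns), component 1 vertical (rows).

## Losses

With x = sCT, w = rsCT, y = target, d = DVF:

* **Perceptual** (on (x, y)): a DISTS-style index
  D = 1 - sum_ij (alpha_ij l_ij + beta_ij k_ij), where l compares global
  per-channel feature means (texture) and k global per-channel feature
  covariances (structure), per stage of a feature pyramid, with
  sum(alpha) + sum(beta) = 1 so that D(x, x) = 0 and D is symmetric. The
  original index uses a pretrained VGG backbone with learned weights;
  since no pretrained weights can be bundled, the default backbone is a
  frozen fixed-seed convolutional pyramid (stages 8/16/32 channels, stride
  2, leaky ReLU) with uniform normalized weights. This preserves the
  index's self-similarity, symmetry and boundedness contracts and is
  regenerated deterministically from its seed at construction. The
  perceptual term compares the *unwarped* sCT to the target — the
  synthesizer's own output — with a flag to use rsCT instead.
* **Intensity** (on (w, y)): Charbonnier, mean sqrt((y - w)^2 + e^2) with
  e = 1e-3; equals e exactly on identical images and tends to L1 as e -> 0.
* **Structure** (on (w, y)): windowed locally normalized cross-correlation
  (box window 9, reflect-padded so affine invariance holds at borders;
  denominator stabilized by 1e-10), returned as 1 - LNCC in [0, 2] so that
  minimization *increases* correlation. The printed global form (a single
  Pearson correlation with sample statistics) is available as
  `global_ncc`; the windowed form is the default because a purely global
  correlation carries no local anatomical signal.
* **Smoothness** (on d): mean squared forward-difference gradient of the
  field; the squared norm sums over the two vector components, differences
  are taken over the valid region, and the two derivative directions are
  averaged — a unit ramp in one component scores exactly 0.5.

Total: L = L_perceptual + 5 L_intensity + 1 L_structure + 1 L_smooth.

## Training

One Adam optimizer (beta1 = 0.5, beta2 = 0.999) over both networks. The
learning rate warms up from 1e-4 to a peak at epoch `warmup_end` (cosine
ramp by default; linear available) and decays along a cosine to zero at
`total_epochs`; the reference schedule peaks at 0.1 at epoch 50 and ends
at epoch 200. Validation (fraction 0.1 of a seeded 0.9/0.1 split) computes
the mean Charbonnier intensity loss between rsCT and target every 10
epochs; the minimizing weights are kept (plain L1 is logged alongside —
the selection criterion is taken as Charbonnier since that is the
framework's intensity loss). Runs too short to reach a validation epoch
score the final weights instead, so a checkpoint always exists.

Ablation modes: M1 — synthesizer only with L1; M2 — joint with L1 on rsCT
+ smoothness; M3 — joint with perceptual + structure + smoothness; M4 —
the full objective.

### Desk-scale profile

All quantitative experiments in the test suite run a deliberately small
configuration chosen once (`desk_profile`): 64x64 phantoms, 32-pixel
training patches, batch 8, synthesizer with base 16 channels / encoder
depth 2 / 2 DTBs / 2 heads, registration network with filters
(16, 32, 32, 32) and 2 residual blocks, 20 epochs with the warm-up peak at
1e-3. The peak of 0.1 from the reference schedule is far too hot for this
small Adam-driven model (it diverges within an epoch); the desk profile
deviates deliberately and the reference values remain the defaults of
`ScheduleConfig`. Encoder depth 2 keeps an 8x8 bottleneck on 32-pixel
patches, which preserves more spatial detail than deeper variants at this
scale.

## Numerics

The networks and losses run on an in-package reverse-mode automatic
differentiation engine over numpy (float32): a dynamic tape with explicit
backward rules for convolution (im2col + BLAS matmul forward,
slice-accumulate col2im backward), depthwise convolution, separable
bilinear resizing, the bilinear warp (scatter-add image gradient;
image-difference field gradient, zeroed where border clamping makes the
output locally constant), softmax, layer normalization and elementwise
primitives. Every primitive is verified against central finite differences
in the test suite. Determinism: all randomness flows through explicit
`numpy.random.Generator` objects seeded from configuration; repeated runs
are bit-identical.

## Phantom generator

The generator emulates the statistical structure the framework assumes,
not the physics that produces it:

* **Clean anatomy**: a body ellipse on an air background (about 40 HU soft
  tissue) containing lung-like (-700), fat (-100), soft-tissue (60) and
  bone (700) elliptical components with per-instance HU jitter, plus
  smoothed texture; clipped to the HU window.
* **CBCT degradation**: radial cupping (60 HU, centre suppressed), a
  linear shading plane (30 HU), about six Gaussian-profile streak lines
  (up to 50 HU, random angle/offset/sign), white noise (25 HU SD) and a
  +20 HU global offset, re-clipped to the window. These amplitudes were
  fixed once so the cohort CBCT-vs-clean MAE lands at the tens-of-HU order
  typical of raw cone-beam images; they are not tuned afterwards.
* **Misalignment**: per-component white noise smoothed by a Gaussian of
  scale 8 px and rescaled so the maximum displacement magnitude is 3 px
  (default), emulating residual deformable-registration error. The target
  equals warp(clean, field) exactly, so registration accuracy can be
  scored against the known field. An optional "cavity-change" event adds a
  large localized radial deformation (default off) to reproduce the known
  failure mode of organ-fullness changes, which residual-misalignment
  correction cannot fix.

What the phantoms do *not* model: projection-domain physics (scatter, beam
hardening from spectra), anatomical variability of real patients, 3-D
continuity across slices, scanner-specific noise correlation. Passing the
desk-scale experiments therefore demonstrates that the training machinery
behaves as designed — the joint model removes exactly the artifact families
it is shown, and registration correction recovers exactly the kind of
smooth misalignment injected — not that clinical image quality figures
would be reproduced.

## Scaled-down experiments and what they show

* **Registration recovery**: 100 training / 20 held-out pairs, fields of
  max 4 px; the registration network alone (40 epochs, lr 1e-3) reaches a
  held-out mean endpoint error of about 1.25 px, against a zero-field
  baseline of about 1.48 px. The averaged error includes the signal-free
  air background, where no image evidence constrains the field and the
  smoothness prior pulls the prediction toward zero while the true field
  is nonzero; interior (body) error is substantially lower than the
  image-wide mean.
* **End-to-end joint training**: 200 pairs, 20 epochs: M4 reduces held-out
  MAE(sCT, clean) by 37-42% relative to MAE(CBCT, clean) across seeds,
  with SSIM rising. The ablation ordering shows the registration benefit
  sharply: synthesis-only M1 reaches about half the error reduction of the
  registration-corrected M2 (roughly 19 vs 12 HU at these settings),
  because M1's pixel loss blurs the network toward the misaligned targets.
* **A desk-scale caveat on the full objective**: with the untrained
  perceptual backbone, M4 (perceptual + structure added to M2's terms)
  lands *above* M2 on MAE (roughly 23 vs 12 HU). The two texture terms
  anchor different geometries — the perceptual index compares the unwarped
  sCT to the target while the local-correlation term compares the warped
  rsCT — and their disagreement propagates through the warp; pairing the
  perceptual term with rsCT (the `perceptual_on_rsct` flag) removes most
  but not all of the penalty. With a semantically trained backbone and
  two orders of magnitude more data and epochs this balance can
  plausibly reverse; at desk scale the full objective buys SSIM-flavoured
  fidelity at an MAE cost, and the reference configuration remains the
  default on the strength of the design it implements, not of this
  small-scale comparison.

## Known limitations

* 2-D slices only; no 3-D context or inter-slice consistency.
* The perceptual backbone is untrained; it provides multiscale statistical
  comparison, not semantically weighted features.
* The registration parameterization is a free-form displacement field with
  a gradient penalty — not diffeomorphic, no folding guarantee.
* Large, topology-changing deformations (the cavity-change events) are out
  of the correction budget by design and remain a documented failure mode.
* The desk-scale profile's absolute numbers depend on the phantom spec;
  only directions and identities are asserted, not clinical magnitudes.
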