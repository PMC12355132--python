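# Methods

This note documents the models and numerical procedures implemented in
`histo25d`, the defaults they run with, and what the synthetic phantoms
do and do not demonstrate about real slide data.

## Problem setting

A needle-core biopsy is serially sectioned into 6–16 ribbons, each
stained with H&E and scanned as an independent 2-D whole-slide image.
The tissue is one physical volume, but every ribbon lands on the glass
with its own rotation, translation and slight scale, plus a smooth
non-rigid distortion from cutting and mounting. The package
reconstructs a "2.5D core": the z-ordered stack of sections
co-registered into one frame at the 20x working resolution
(0.5 um/px), so that a pathologist can scroll through depth and a model
can consume 256x256xZ volumetric patches.

## Morphology-preserving alignment

The central design constraint is that registration must not deform
diagnostic morphology. It is enforced structurally, in two stages:

1. **Serial rigid stage — similarity transforms only.** A similarity
   transform (rotation, isotropic scale, translation; never shear or
   reflection) cannot change shapes. Keypoints are SIFT
   (scikit-image, full two-octave pyramid), restricted to the tissue
   mask; candidate assignments are mutual-nearest-neighbour matches
   under Lowe's ratio test (0.75); the per-pair transform is a RANSAC
   consensus fit (fixed seed, 3 px inlier tolerance, 500 trials)
   followed by a least-squares refit on the inliers and one tightening
   pass at half the tolerance. The matcher sits behind a functional
   interface so a learned assignment model can replace it without
   touching the fit. Registration is serial: section 0 is the
   reference, and each section k is registered against the *rendered*
   (already-registered) image of section k−1, so each returned
   transform maps native section coordinates directly into the
   reference frame and chained drift is measured against the rendering,
   not accumulated blindly. Transforms estimated on a downsampled level
   propagate to finer levels by scaling the translation with the
   downsampling factor; angle and scale are resolution-independent.

2. **Non-rigid stage — boundaries only.** Intensity-driven deformable
   registration would bend nuclei and glands to maximize texture
   agreement. Instead, each rigidly aligned section is reduced to the
   contour of its tissue mask — including the rims of gland lumina,
   which are genuine tissue boundaries and the only information that
   pins the field down *inside* the ribbon — and the contour to a
   signed distance transform (SDT, negative inside, clipped at ±30 px).
   A free-form cubic B-spline displacement field is then fitted by
   minimizing

       mean[(SDT_moving(x + d(x)) − SDT_fixed(x))²]
         + λ_bend · (control-grid bending energy)
         + λ_disp · (mean squared control displacement)

   with L-BFGS-B, coarse-to-fine over three control grids
   (128 → 64 → 32 px), 150 iterations total, λ_bend = 0.03,
   λ_disp = 0.01. The analytic gradient uses the exact adjoint of the
   tensor-product B-spline basis (two small matrix products), so
   each iteration costs one dense resampling. Only boundary-derived
   data enters the objective; interior texture is never read, and the
   final field is applied once to the full-colour image.

   The displacement prior λ_disp deserves a note: after the rigid
   stage the residual motion is small, and without this term the flat
   (clipped) far field lets large smooth displacements go unpunished —
   in degenerate cases (e.g. mask topology differing between sections
   because a lumen is visible in one section only) the optimizer can
   otherwise "teleport" structures tens of pixels. The prior bounds
   that failure mode; it does not remove it, which is a known
   limitation for real sections whose lumen topology genuinely changes
   with depth.

   All weights were chosen on phantom stacks and are config-exposed;
   they are this package's choices, not reconstructed settings of any
   other software.

### Registration error statistic

Per adjacent pair, the error is the median distance in microns between
matched keypoints mapped into the common frame; per core, the mean of
pair medians weighted by each pair's match count. All three conditions
(unregistered, rigid, rigid+non-rigid) are scored on the *same* match
population — every mutual-ratio match within 5x the fit tolerance of
the similarity fit. Restricting to strict RANSAC inliers would censor
exactly the non-rigid displacement signal the statistic exists to
measure; the 5x gate only removes gross descriptor mismatches, against
which the median is in any case robust. Non-rigid points are mapped
through the backward field by fixed-point inversion (q ← p − d(q)),
which converges because |d| is far below the control spacing.

## Tissue masks and patching

Tissue is separated from the white slide background in HSV space:
pixels with saturation above 0.05 and hue above an Otsu threshold
(H&E pinks and purples sit high on the hue circle; an explicit window
can override) are tissue; stained specks under 16 px are removed and a
single morphological closing (disk radius 5) fills small gaps without
welding noise into tissue. Ribbons are 8-connected components above
0.1% of the image area, ordered top-to-bottom then left-to-right; the
z-order across slides is the caller's to supply.

The co-registered core is tiled on a non-overlapping grid anchored at
the top-left of the tissue-union bounding box. A tile is kept iff its
tissue fraction — the mean over all Z sections of the in-window tissue
pixel fraction — is strictly greater than 0.6; a tile at exactly 0.6 is
discarded. Partial edge tiles are discarded.

## Divided depth/space attention encoder

The encoder is a NumPy reference implementation at desk scale (default
D = 64, A = 4 heads, L = 2 blocks, P = 8 px patches). Each 2.5D patch
(F slices) is cut into N = (H/P)(W/P) sub-patches per slice; each is
flattened, linearly embedded and given a learned positional embedding
indexed by (spatial site, slice); one classification token is
prepended. Each block applies, with pre-norm residuals:

* **depth attention** — query (p, t) attends to the classification key
  and the F tokens at the same site p (F+1 logits, scaled by 1/√Dh);
* **spatial attention** — fresh q/k/v from the depth output; query
  (p, t) attends to the classification key and the N same-slice tokens;
* a 2-layer GELU MLP (width 4D).

The divided key sets leave the classification token's own path open;
here it passes through depth attention unchanged and attends over all
tokens in the spatial stage, consistent with its appearance as a key in
both stages. Weights are drawn from a seeded generator; the parameter
count is a pure function of the configuration and is regression-tested.

Correctness is established against an independent oracle: a loop-based
dense attention restricted by the same key sets must agree to 1e-5
across randomized configurations, and every attention row must sum to
one.

### Attention rollout

For interpretation, the per-layer head-averaged weights are combined as
W[(i,j),(p,q)] = S[i,j,p] · T[p,j,q] — the unique two-hop path a token
has to every (site, slice) under the factorization — giving a
row-stochastic (N·F)x(N·F) matrix per layer; the rollout attribution is
the ordered product across layers. The classification key's share is
removed and rows renormalized before combining, since the formula is
defined on patch tokens. An optional residual-mixing variant averages
each layer with the identity; it is off by default because the
combination formula carries no identity term.

## Momentum self-distillation

The encoder is pretrained student/teacher style: global views (large
random crops, here 60–100% of the patch area) pass through the teacher;
the student sees global and local (20–50%) views, all resized to one
input size so the token geometry is shared, with full depth kept in
every view. The loss is the cross-entropy between the teacher's
centered, sharpened output distribution (temperature 0.04) and the
student's (temperature 0.1), summed over teacher-view/student-view
pairs excluding identical views. The teacher's weights are an
exponential moving average of the student's (momentum 0.996); the
center is an EMA (0.9) of teacher logits. Student gradients come from a
hand-written reverse pass through the full encoder (layer norm,
masked dense attention, GELU MLP, projection head), verified against
central finite differences to ~1e-7 relative error, and applied with
Adam (lr 5e-4). The masked dense forward used for training is tested
equal to the divided-attention forward.

This component is a training-mechanics reference: a 30-step run on
eight small patches demonstrates a decreasing loss, not a useful
representation.

## ABMIL grading

A core is a bag of patch feature vectors with one weak label. Gated
attention pooling scores each instance with w·(tanh(Vh) ⊙ σ(Uh))
(hidden width 128 by default), softmax-normalizes the scores, and
classifies the attention-weighted mean feature with a linear layer —
permutation-invariant by construction, with the attention weights as
the localization map. Grade groups {benign, GG1, ..., GG4/5} binarize
to clinically significant at GG ≥ 2. Training is per-bag Adam on
cross-entropy with early stopping on a held-out split. The synthetic
validation task draws background instances from N(0, I) and marks a
bag positive iff it contains a few instances shifted by 3σ along one
feature axis — a separable task on which a correct implementation must
reach high AUC and place its top attention on signal instances.

Model comparison uses McNemar's χ² = (b−c)²/(b+c) on the discordant
counts of paired correctness vectors (continuity correction optional,
off by default); reader agreement uses quadratic-weighted Cohen's
kappa.

## The phantom generator

Every registration claim is tested against synthetic serial-section
stacks with exact ground truth. A phantom core is an elliptical
H&E-like ribbon (eosin-pink stroma with a low-frequency intensity
field, hematoxylin-purple nuclear speckle, white elliptical gland
lumina) on a white canvas. Defaults: 8 sections, 320 px canvas,
6 glands, per-section rotation up to ±10°, scale in [0.97, 1.03],
translation up to ±20 px (sampled about the canvas centre), smooth
warps of 6 px peak amplitude on a 64 px control grid, Gaussian sensor
noise (sd 4), and a slight depth drift of the nuclear speckle so
adjacent sections resemble, but do not equal, each other. Landmarks
are fixed interior points pushed through the exact corruption maps;
tissue masks are stored per section, and the tissue fraction matches
the analytic ellipse areas. Equal seeds give bit-identical stacks.

What the phantoms do **not** emulate: realistic nuclear texture and
stain variation, tissue tears and folds, pen marks, true 3-D structure
change between sections beyond a smooth texture drift, multi-ribbon
slides with ambiguous z-order, and depth-varying lumen topology (a
gland appearing or vanishing between sections). Passing the phantom
suite therefore demonstrates the correctness of the geometry,
optimization and bookkeeping, not robustness to every histological
artifact.

## Problem sizes

Tests and the acceptance script run at desk scale on one CPU: 320 px
phantom canvases (about 1/30 the linear size of a real 20x core
image), 8-section stacks, encoders with ≤ 32–64 embedding dimensions,
and MIL training sets of a few hundred bags. These sizes were chosen so
the full suite re-runs from scratch in minutes while every algorithmic
path — including the multi-resolution optimizer and the full backprop —
is exercised.

## Known limitations

* The non-rigid stage assumes consistent mask topology across sections;
  the displacement prior bounds, but does not eliminate, the damage
  when a lumen is present in one section's mask only.
* Boundary-driven fields are underdetermined deep inside large
  featureless tissue regions; accuracy there rests on the smoothness
  prior and recovered gland rims.
* The serial chain accumulates per-link error as a random walk;
  stacks much deeper than ~16 sections would need a drift correction
  against the reference.
* The encoder and MIL components are reference implementations in
  NumPy; they validate the mathematics, not throughput, and no trained
  weights are shipped.
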