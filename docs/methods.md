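# Methods

`histostack` reconstructs a 3D multi-contrast volume from serially sectioned,
differently stained 2D histology by anchoring every section to its blockface
photograph, and coaligns a 3D MRI volume to the same space.  This note
documents the models, the defaults and why they are set where they are, what
the synthetic phantom does and does not emulate, and the numerical choices a
user should know about.

## The reconstruction model

Serial sectioning yields, per physical slice, one undistorted blockface
photograph (taken on the frozen block before the cut) and, on an interleaved
sampling plan, one stained section per stain.  Mounting and staining impose
smooth nonlinear in-plane distortions plus a small affine jitter on each
section; the blockface stack, restacked with no registration at all, defines
the common 3D space.

Each stained section is registered to a weighted set of targets:

* its own blockface image (weight 1) — the geometric anchor;
* the nearest previously coregistered section of the same stain and that
  section's tissue-boundary map (weight 1/2 each);
* the two nearest previously coregistered sections of any stain and their
  boundary maps (weight 1/4 each);

with "previously coregistered" limited to a sliding window of three slices on
the already-visited side of the current sweep.  Because every registration
depends only on upstream results, the stack is processed like a Markov chain:
a rostral-to-caudal sweep followed by a caudal-to-rostral sweep, the pair
iterated three times.  After every sweep each section reverts to its archived
best transform, scored by mutual information (MI) against its blockface
image, so the archive is monotone and a degraded registration never seeds the
next pass.  The blockface anchor is what prevents the cumulative bending
("banana effect") that purely neighbor-chained schemes produce; the package
demonstrates this by ablation (blockface weight 0) in its tests.

## The pairwise registration engine

The engine maximizes a weighted sum of similarity terms over one or more
fixed targets, returning an affine-plus-dense-displacement transform in the
pull-back convention (output-grid coordinates map into the input raster).

* **Similarity.** Intensity channels use histogram MI (32 equal-width bins
  over the observed range, fewer on small pyramid levels); feature channels
  (boundary maps, which are same-modality on both sides) use Pearson
  correlation, because a histogram metric on a mostly-flat ridge raster is
  ill-conditioned.
* **Forces.** Cross-contrast demons forces are obtained by remapping the
  warped moving image through the conditional mean of the target intensity
  given the moving intensity (a correlation-ratio-style transfer function
  re-estimated every iteration), then applying symmetric (ESM-style)
  demons steps.  Per-target force fields are normalized to a common scale
  before weighting, so no channel dominates by raw gradient magnitude.
  Boundary-map channels contribute to iterate *selection* only, not to the
  forces: ridge forces computed against imperfectly aligned chained
  neighbors were found to compound alignment errors along the stack.
* **Optimization.** Coarse-to-fine over a halving pyramid (default schedule
  64, 32, 16, 8, 4, 2, 1, truncated so every level keeps at least 16 px per
  axis and at most `n_scales` levels remain).  At the coarsest retained level
  a global affine is estimated first — translation + rotation in 2D;
  translation + Euler rotations + scale, refined to a full 12-parameter
  affine, in 3D — by Powell search on MI, initialized by phase correlation
  of the contrast-remapped image.  Demons iterations then refine a dense
  field with fluid (force) smoothing sigma 4 px and diffusion (field)
  smoothing sigma 3 px, steps peak-normalized to 2 px with a trust-region
  gain that backs off when the metric stalls.  The best iterate by the
  weighted metric is kept per level, and the best level result by
  full-resolution metric is returned; warm starts (non-identity
  initialization) skip the coarse levels and can never return a worse
  transform than their initialization.
* **Defaults** (`RegistrationParams`): 60 iterations per level,
  convergence tolerance 1e-4 relative metric change, 25 iterations on warm
  restarts.  These were chosen by recovery of known phantom warps; with
  them a single cross-contrast pairwise registration recovers a mean-10-px
  smooth warp to ~1.4 px mean endpoint error in ~0.6 s on one CPU core.

## Intensity harmonization and gap interpolation

Within a stain, slow intensity drift across staining sessions is removed by
chaining per-slice linear (gain/offset) corrections rostral to caudal: each
measured slice is matched to its already-matched predecessor over their
joint tissue support with a *symmetric* (reduced-major-axis) fit — an
ordinary regression would attenuate the gain under noise.  The first slice
is the untouched reference, so the stain's dynamic range is preserved; no
nonlinear intensity remapping is applied, by design, at the cost of a small
residual drift.

Slices a stain did not sample are filled by guided nonlocal means along z:
each missing pixel is a weight-normalized average of the same pixel in the
channel's measured slices within a search depth of 3 slices, with weights
`exp(-||patch difference||^2 / h^2)` computed on a fully sampled guide
volume (the blockface by default) over 5x5 patches.  Patch distances are
shifted by the per-pixel best distance before exponentiation (numerically
stable, scale-free), and `h^2` defaults to the median positive shifted
distance.  Gaps wider than the search depth fall back to the nearest
measured slice and are flagged `missing`; all interpolated slices carry an
`interpolated` provenance flag.

## 3D MRI alignment

The MRI volume is resampled to the blockface grid (it is acquired at 400 um,
the blockface space is 200 um), then registered in three deformable stages
with strictly decreasing field regularization (sigmas 4, 2, 1 voxels, 25
iterations each), each stage seeded by the previous and rejected if it
degrades the metric.  The metric support is restricted to the dilated
blockface tissue mask — the background says nothing about the warp — minus
an optional exclusion mask of ventricle-scale interior holes, whose
appearance in blockface images is unreliable.  Skull stripping resamples
the MRI through the recovered transform and zeroes it outside the blockface
mask.

Known limitation: on the synthetic benchmark (cross-contrast, mean-3-voxel
smooth warp) the staged alignment converges to ~1.5 voxel mean endpoint
error rather than sub-voxel.  Direct probes show that in several scenarios
the MI of the *recovered* alignment matches or exceeds the MI evaluated at
the exact ground-truth inverse warp, i.e. the residual sits at or below the
similarity metric's information floor for piecewise-constant contrast at
this noise level, and no MI-driven search could be expected to cross it.

## Feature maps, QC and microstructure

* **Tissue masking.** The background intensity is estimated robustly from
  the raster border (median and MAD); foreground is any pixel deviating by
  more than 6 noise SDs (at least 5% of the dynamic range), lightly closed,
  reduced to the largest connected component and hole-filled.  Interior
  holes are kept separately.  A bimodal (Otsu) split is deliberately not
  used: with several tissue classes per stain, an Otsu threshold can land
  between tissue modes and classify a whole class as background.
* **Boundary map.** `exp(-d^2 / 2 sigma^2)` of the unsigned Euclidean
  distance to the mask contour; sigma defaults to 5 px (a smooth capture
  range for registration and QC).  The stack aligner uses sigma 2 px for
  its registration channels: the sharper ridge is less biased by
  warp-induced ridge-width distortion.
* **Vessels.** Vessel cross-sections are interior holes with equivalent
  radius in a configurable range (default 1.5-5 px) and solidity >= 0.8;
  ventricle-scale holes fail the radius filter, tears fail solidity.
  Centroids are intensity-weighted.
* **QC.** For consecutive measured sections, within and across stains, the
  symmetric mean contour distance (average nearest-point distance, both
  directions; Hausdorff reported as a secondary column) and the mean
  distance of mutually-nearest matched vessel centroids are tabulated in
  micrometers.  Records above 2 mm are flagged: distances of that size
  indicate missing structure, not misregistration.  Blockface-derived
  features are excluded from QC because blockface background separation
  loses fine detail.
* **Structure tensor.** Gaussian-derivative gradients (sigma 1 px),
  tensor-windowed at sigma 8 px — about the size of a 200-um aggregation
  cell at the fine section scale — eigendecomposed into the dominant
  orientation (degrees in [0, 180)) and anisotropy `1 - lambda2/lambda1`.
  The window is large enough that isotropic noise yields median anisotropy
  below 0.2 (smaller windows bias anisotropy upward).  Aggregation to the
  blockface grid warps the *tensor* components through each section's
  transform, reorients them with the inverse local Jacobian, and averages
  tensors per voxel — never angles, which wrap at 0/180 degrees.
* **Vessel density.** Detected vessel masks of all stains are warped to the
  blockface grid, accumulated per voxel, divided by the number of
  contributing sections per slice, and smoothed with a normalized Gaussian
  (mass-preserving); values are volume fractions in [0, 1].

## The synthetic phantom

The phantom generates everything the pipeline consumes, with exact ground
truth, and its defaults define the package's validation conditions:
128x128 pixels in-plane, 60 slices at 200 um isotropic, three tissue
classes, eight non-intersecting tubular vessels of radius 2-4 px.

* **Geometry.** The brain support is a noise-perturbed ellipsoid whose
  z-semi-axis is 1.5x the stack depth: the sampled stack covers the central
  portion of a longer specimen, so the tissue outline changes slowly from
  slice to slice, as 200-um serial sections of a real brain do.  Tissue
  classes are quantile bands of a band-limited noise field with physically
  isotropic feature scale (in-plane sigma 16 px, the same in z), again
  matching the interslice continuity real tissue exhibits.  Vessels are
  smooth, mostly rostro-caudal tubes, trimmed so every cross-section is a
  complete disk inside tissue.
* **Contrasts.** Five stains plus a sixth blockface contrast are rendered
  by per-class intensity lookup, with per-class Gaussian noise (SD 5, i.e.
  ~5% of the tissue-background contrast), a linear rostro-caudal intensity
  drift of 0.5 units/slice on tissue (background constant), and vessels
  rendered at background intensity.  The blockface lookup is unrelated to
  every stain, so all registration against it is genuinely cross-contrast.
  Class means stay below ~180 against backgrounds of ~230-242 so that the
  drift can never push a tissue class into the background band.
* **Corruption.** Each stained section gets a band-limited random
  displacement field (smoothing sigma = 1/5 of the in-plane extent) scaled
  to mean magnitude 10 px, checked for positive Jacobian (and automatically
  rescaled with a warning if it would fold), plus affine jitter up to
  2 degrees and 3 px.  Sampling plans follow interleaved intervals (three
  stains at 1:3 with staggered offsets covering every slice, two at 1:6);
  damaged slices are dropped from stains but kept in the blockface.
* **Determinism.** All randomness derives from the spec seed through
  per-(slice, stain) seed sequences (CRC-stable across processes);
  identical specs produce bit-identical datasets.
* **What it does not emulate.** Cellular-scale texture, stain
  inhomogeneity within a class, freezing artifacts, air bubbles, tissue
  tears, or anatomically realistic shapes.  Passing recovery tests on the
  phantom therefore demonstrates the pipeline's geometric and contrast
  logic under controlled, known-truth conditions — not performance on any
  particular real specimen, where distortion magnitudes and mask quality
  may differ.

## Problem sizes used in validation

The test-suite reconstructs the default 128x128x60 five-stain phantom
(~80 stained sections) with three forward-backward iterations, runs the
banana-effect ablation on a 64x64x40 single-stain stack, and benchmarks the
3D MRI alignment on a 64x64x48 volume; the acceptance script repeats these
computations from scratch at the same sizes.  These sizes keep every stage's
behavior measurable (multi-scale pyramids, interleaved sampling, anchored
sweeps) while each full run completes in minutes on a single core.
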