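# Methods

`jointatlas` segments the left atrium (LA), its four pulmonary veins (PVs)
and the left atrial appendage (LAA) from 3D bright-blood angiography by
multi-atlas registration, and implements two registration strategies behind
one configuration:

* **pairwise** (baseline): each atlas image `A_i` is registered
  independently to the target `I` by maximizing mutual information (MI);
  the atlas labels are mapped through the fitted transforms and fused by
  majority voting on the target grid.
* **joint** (the method of interest): one optimization over the ensemble
  `mu = (T_0, T_1, ..., T_N)` — a transform for the target *and* each atlas —
  minimizing the intensity variance across the warped group,

  `C(mu) = sum_v [ (I(T_0(v)) - M(v))^2 + sum_i (A_i(T_i(v)) - M(v))^2 ]`,

  where `M` is the voxelwise group mean, the *mean-shape image*: an average
  in intensity and, through the transforms, in shape.  Labels are fused on
  the mean-shape grid and carried back to the target through the numerically
  inverted target transform.

Both are optionally followed by a 3D Chan–Vese level-set refinement of the
fused segmentation.

## Transforms and resampling

All transforms map reference-space points into the moving image's space
(pull-back convention); coordinates are physical millimetres, voxel indices
0-based, with `physical = origin + index * spacing` along matching axes.

* **Affine**: 3 translations, 3 ZYX Euler rotations about the image centre,
  and one isotropic scale (7 parameters).  The scale and rotations act about
  the image centre; the model deliberately has no shear or per-axis scaling.
* **B-spline free-form deformation**: cubic, displacement
  `d(x) = sum_k p_k beta3((x - x_k)/sigma)` on a regular control-point
  lattice with spacing `sigma` (default 10 mm), extended at least two
  control points beyond the covered domain so every interior point has full
  4x4x4 support.  Full-grid evaluation is routed through cubic-spline
  interpolation of the coefficient arrays (`map_coordinates`,
  `prefilter=False`), which is algebraically identical to the 64-point
  tensor-product sum (asserted to 1e-9 in the tests).
* **Inversion** is a fixed-point iteration on the dense inverse displacement
  field, `d'(y) <- -d(y + d'(y))`, evaluated exactly through the forward
  transform; the result is a trilinearly interpolated displacement-field
  transform.  The residual `max |T'(T(x)) - x|` is checked on a subsampled
  grid (default tolerance 0.1 mm, 50 iterations), excluding points whose
  forward image leaves the field's domain, where the inverse would be a
  clamped extrapolation.  Because the residual is dominated by the *field
  interpolation* error, the grid the inverse lives on must be fine enough:
  back-propagation builds it on the target grid refined to <= 2.5 mm per
  axis, and the phantom's invertibility check uses a uniform 2 mm lattice.

## Registration framework

Both modes share one hierarchy: an affine stage, then a B-spline stage, each
run coarse-to-fine over a Gaussian image pyramid (default 3 levels,
downsampling by powers of two).  Images are first normalized linearly to
0–255.  Each stage is optimized by stochastic gradient descent: per
iteration, `samples_per_iteration` (default 2048) random points are drawn
uniformly over the reference grid, the metric and its analytic gradient are
estimated on that batch, and parameters move along the negative gradient
with a decaying gain `a/(A + k)^alpha` (default `a = 4` mm, `A = 50`,
`alpha = 0.602`).

Two stabilizers around the raw stochastic gradient, both chosen after
observing the optimizer's behaviour on synthetic groups (the underlying
citation for the optimizer prescribes the family, not the implementation):

* **gradient averaging** — an exponential moving average (momentum 0.9,
  bias-corrected).  Without it, a group that starts near-aligned
  random-walks away from its optimum: a direction-normalized step at zero
  expected gradient still moves at full gain, and the sampling noise
  diffuses the ensemble faster than the weak restoring gradient can pull it
  back.
* **running-max normalization** — steps are the smoothed gradient divided by
  the largest smoothed-gradient magnitude seen so far in the stage, times
  the gain; so the maximum parameter step is `gain` (mm-equivalent) and
  steps decay to zero as the optimum is approached.  Affine parameters are
  additionally scaled so one unit of scaled rotation/scale moves points
  about one millimetre (scaling by the half-diagonal image extent).

The final parameters of each stage are the average of the iterates over the
last quarter of the iterations, which centres the residual stochastic
dither.

**MI metric (pairwise).** Parzen-window joint histogram with 32 bins:
zero-order window on the fixed intensity, cubic B-spline window on the
moving intensity; the cost is `-MI` (the registration maximizes MI — the
objective is stated as a minimization, so the sign is fixed here once) and
its gradient chains the window derivative with the moving-image spatial
gradient (precomputed central differences, sampled linearly) and the
transform Jacobian.

**Variance metric (joint).** The batch estimate of the group variance; its
derivative with respect to member `j`'s intensity is simply
`2 (I_j - mean)/S` because the mean's own dependence cancels
(`sum_j (I_j - mean) = 0`).  The metric is blind to a common deformation of
the whole group, so the ensemble is **gauge-fixed**: after every iteration
the group-mean parameter update is subtracted (exactly zero mean
displacement for the shared-lattice B-spline stage; mean of the scaled
parameter updates for the affine stage).  The reference grid of the
mean-shape image is the target's geometry; all B-spline stages in a group
share one lattice so the gauge is well defined.

Determinism: a single seeded RNG drives all sampling; identical seed,
configuration and inputs reproduce transform parameters bitwise.

## Fusion

Atlas labels are propagated with nearest-neighbour interpolation — to the
mean-shape grid (joint) or the target grid (pairwise) — and fused by
per-voxel majority vote over all seven label values jointly, so the PV/LAA
identities survive end-to-end.  Ties break toward the smaller label value
(background wins), a conservative rule.  One fusion implementation serves
both pipelines.  In joint mode the fused segmentation returns to the target
through the inverted target transform.

## Level-set refinement

Chan–Vese (region-based, no edges) on the binary union of the fused
foreground; after convergence each foreground voxel takes the label of the
nearest originally fused voxel (Euclidean distance transform), preserving
the structure identities and partitioning the refined mask exactly.

Numerics (the energy's authors leave the discretization open; these choices
are this package's):

* `phi` is the signed distance of the initialization (negative inside at the
  API; the solver works positive-inside internally), reinitialized every 20
  iterations; the evolution runs in voxel units.
* The smoothed Heaviside is the **compact-support sine ramp** over
  `|z| <= epsilon`, not the arctan form: the arctan's `1/z` tails let the
  vast background volume of a 3D image contaminate the inside mean (on a
  16^3 two-level test the inside mean lands halfway between the classes),
  while the compact form reproduces region means to machine precision on a
  crisp partition.  `epsilon` defaults to **1.5 voxels** because the compact
  delta vanishes at `|phi| = 1` — exactly where a freshly reinitialized
  front's neighbours sit — so `epsilon = 1` freezes the evolution.
* The update is `phi += dt * (delta/delta_max) * clip(F / (0.2 f), -1, 1)`
  with `F` the pointwise force (curvature, volume, and the two data terms)
  and `f` the interface-weighted mean `|F|`: any clearly signed force moves
  the front at `dt` (default 0.1) level-set units per iteration regardless
  of the intensity scale, which also makes the `mu = nu = 0` flow exactly
  covariant under affine intensity rescaling.
* Convergence is a **windowed** check: stop when the per-iteration
  sign-change fraction stays below `convergence_tol` for a full
  reinitialization window.  The tolerance defaults to 1e-5 of the volume: a
  regrowing PV tip flips only a few voxels per iteration (~5e-6 of a
  96x96x64 grid), so a looser tolerance halts exactly the distal-part motion
  the refinement exists for.
* Defaults: `lambda1 = lambda2 = 1`, `mu = 0.2 * 255^2` (the classic 0.2 for
  unit-range images, rescaled), `nu = 0`, 500 iterations.
* The reported `energy` uses the crisp partition (`phi < 0`), with the
  surface term as the exposed-voxel-face count; the evolution descends the
  smoothed surrogate.  The crisp form makes "perfect two-constant fit has
  zero energy" exact.

With the test-scale half-resolution grids the PV tubes are only ~1.6 voxels
across; there the curvature term visibly erodes thin tubes and refinement
can lower tube Dice even when it helps at native resolution.  This is a
resolution effect of the model, not an implementation artifact.

## Evaluation

* Dice `2|A n B|/(|A| + |B|)`; both-empty pairs score 1 by convention.  The
  whole-LA score is the Dice of the label unions, not an average of
  per-structure values.
* Surfaces are marching-cubes 0.5-isosurfaces in physical mm of the
  one-voxel-padded mask, extracted after a slight Gaussian smoothing (0.7
  voxel) of the indicator to suppress the staircase area bias of a raw
  voxelization (a raw binarized sphere overestimates area by ~8%); objects
  too small to survive the smoothing fall back to the raw indicator.
* S2S is the mean over the automatic surface's vertices of the **exact**
  point-to-triangle distance to the reference surface — directed
  (auto → reference), per the benchmark definition this follows; a
  `symmetric=True` flag averages both directions.  Candidate triangles are
  pruned with two KD-trees (vertex distances bound the minimum from above,
  centroid distances minus circumscribing radii from below), so the exact
  distance is only evaluated where it can win; the tests assert equality
  with a brute-force min-over-all-triangles oracle to 1e-9.

## Synthetic phantom

The generator emulates the structure the method assumes, not patient
anatomy: an ellipsoidal chamber (semi-axes 26/22/20 mm), four thin tubes
(radius 4 mm, length 24 mm) attached at fixed ostia, and a spherical
appendage bump (radius 7 mm), on a 96x96x64 grid at 1.25x1.25x2.27 mm.  The
thin distal tubes deliberately reproduce the failure mode that motivates the
joint method: small structures far from the centroid on which independent
registrations disagree.

Appearance mimics bright-blood angiography: blood pool 200, background 30,
and a 2-voxel myocardial rim at 65 — dark enough that the two-phase
piecewise-constant refinement model groups the rim with the background
(a rim at the class midpoint would be absorbed into the blood pool and
violate the model the refinement assumes).  Per-case additive Gaussian noise
(sigma 8, SNR ~25 against the blood pool) and a smooth multiplicative bias
field (+-10%, cubic upsampling of a 4^3 Gaussian draw).

Inter-subject variation: each case is the template pulled back through an
independent random B-spline warp (20 mm lattice, coefficients
N(0, (amplitude/2.5)^2) clipped to +-amplitude; default amplitude 6 mm,
safely below the 0.4*sigma invertibility bound, and every warp is verified
invertible to 0.1 mm).  Image and labels share the field, so ground truth
and generating transforms are known exactly.  "Outlier" atlases use larger,
smoother warps (12 mm coefficients on a 30 mm lattice) to emulate subjects
far from the group.

What the phantom does **not** model: acquisition physics, gating artifacts,
anatomical topology variants (e.g. common PV ostia), intensity
inhomogeneity beyond a smooth bias, or inter-observer label noise.  Passing
tests therefore demonstrate the mechanics and the comparative behaviour of
the two strategies under controlled variation, not clinical-grade accuracy.

## Problem sizes and study configurations

The registration test problems run at two scales chosen as the package's
test conditions: single-pair recoveries at the native 96x96x64 grid, and
group studies at 48x48x32 over the same physical extent.  Iteration counts
in tests and in `scripts/acceptance.py` (300–600 B-spline iterations per
level, 100–150 affine) are reduced from the 1000-per-level default;
recovery errors at these counts are well inside the asserted bounds.

The group-variance-reduction figure is measured on the noise-free generator
configuration: with the default noise, additive noise alone accounts for
~75% of the initial group variance (926 of 1244 measured at 48x48x32), an
irreducible floor no registration can remove, so the reduction is only
meaningful when the variance is alignment-driven.  Warp recovery is also
checked on the default noisy configuration.

## Known limitations

* The groupwise gauge (zero-mean parameter update) controls drift but does
  not pin the mean shape to any anatomical norm; the mean-shape image is
  defined up to the residual gauge freedom absorbed by iterate averaging.
* The level set treats the volume as isotropic voxels; on strongly
  anisotropic grids the effective smoothing differs per axis.
* MI uses a fixed 0–255 range after normalization; images with heavy-tailed
  histograms would deserve percentile normalization, which the phantom does
  not exercise.
* `invert_transform` assumes the forward transform is diffeomorphic on the
  domain; folding warps fail the residual check rather than being repaired.
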