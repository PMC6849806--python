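"""Pairwise and joint-atlas (groupwise) registration.

Two registration modes share one hierarchical framework — affine stage, then
B-spline free-form deformation, over a coarse-to-fine image pyramid, driven
by stochastic gradient descent with a decaying gain:

* **pairwise** — each atlas is registered to the target independently by
  maximizing mutual information (the cost minimized is ``-MI``);
* **joint** — the target and all atlases are registered simultaneously by
  minimizing the intensity variance across the group.  The voxelwise average
  of the warped group is the *mean-shape image*: an average in intensity and,
  through the transforms, in shape.  Because the variance cost is invariant
  to a common deformation of the whole group, the ensemble is gauge-fixed by
  removing the group-mean parameter update after every iteration.

All transforms returned map reference-space (target) points into the
respective moving image's space (pull-back convention, see
:mod:`jointatlas.transforms`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .config import RegistrationConfig
from .transforms import (
    AffineTransform,
    BSplineTransform,
    CompositeTransform,
    bspline_kernel,
)
from .volumes import Grid, ImageVolume

__all__ = [
    "GroupTransformEnsemble",
    "normalize_intensity",
    "mutual_information",
    "group_variance",
    "mean_shape",
    "register_pairwise",
    "register_joint",
]


# ---------------------------------------------------------------------------
# similarity metrics (public, batch form)
# ---------------------------------------------------------------------------

def normalize_intensity(img: ImageVolume, range: tuple[float, float] = (0.0, 255.0)) -> ImageVolume:
    """Linearly map the image's intensity extrema onto ``range``.

    A constant image maps entirely to the lower bound.
    """
    lo, hi = float(range[0]), float(range[1])
    vmin = float(img.data.min())
    vmax = float(img.data.max())
    if vmax == vmin:
        data = np.full_like(img.data, lo)
    else:
        data = lo + (img.data - vmin) * (hi - lo) / (vmax - vmin)
    return ImageVolume(data, img.spacing, img.origin)


def mutual_information(a: ImageVolume, b: ImageVolume, bins: int = 32) -> float:
    """Mutual information (bits) from a joint histogram with ``bins``
    equal-width bins per image over each image's own range."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"grid mismatch: {a.data.shape} vs {b.data.shape}")
    h, _, _ = np.histogram2d(a.data.ravel(), b.data.ravel(), bins=bins)
    p = h / h.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (pa @ pb)[nz])))


def _check_common_grid(warped: list[ImageVolume]) -> None:
    if not warped:
        raise ValueError("empty image group")
    g0 = warped[0]
    for w in warped[1:]:
        if not g0.same_grid(w):
            raise ValueError("all group images must share one grid")


def group_variance(warped: list[ImageVolume]) -> float:
    """Variance-over-group metric: the per-voxel sum of squared deviations of
    each group member from the group mean, averaged over voxels.

    The voxel average is a constant factor relative to the plain sum and does
    not move the optimum; it makes values comparable across grid sizes.
    """
    _check_common_grid(warped)
    stack = np.stack([w.data for w in warped])
    dev = stack - stack.mean(axis=0)
    return float(np.sum(dev * dev, axis=0).mean())


def mean_shape(warped: list[ImageVolume]) -> ImageVolume:
    """Voxelwise arithmetic mean of the warped group — the mean-shape image."""
    _check_common_grid(warped)
    stack = np.stack([w.data for w in warped])
    g = warped[0]
    return ImageVolume(stack.mean(axis=0), g.spacing, g.origin)


# ---------------------------------------------------------------------------
# ensemble container
# ---------------------------------------------------------------------------

@dataclass
class GroupTransformEnsemble:
    """The joint parameter vector: one transform per group member.

    Index 0 is the target image, indices ``1..N`` the atlases; all map points
    of the common reference grid (the mean-shape grid) into the respective
    image's own space.
    """

    transforms: list
    reference_grid: Grid

    def __post_init__(self) -> None:
        if len(self.transforms) < 3:
            raise ValueError("an ensemble needs the target plus at least two atlases")

    @property
    def n_atlases(self) -> int:
        return len(self.transforms) - 1


# ---------------------------------------------------------------------------
# internal machinery
# ---------------------------------------------------------------------------

def _pyramid(img: ImageVolume, n_levels: int) -> list[ImageVolume]:
    """Coarse-to-fine Gaussian pyramid; level ``i`` is downsampled by
    ``2**(n_levels-1-i)`` with matching pre-smoothing."""
    levels = []
    for i in range(n_levels):
        f = 2 ** (n_levels - 1 - i)
        if f == 1:
            levels.append(img)
            continue
        sm = gaussian_filter(img.data, sigma=f / 2.0)
        data = sm[::f, ::f, ::f]
        spacing = tuple(s * f for s in img.spacing)
        levels.append(ImageVolume(data, spacing, img.origin))
    return levels


class _MovingImage:
    """A moving image with precomputed spatial gradient, sampled at
    arbitrary physical points by linear interpolation (0 outside)."""

    def __init__(self, img: ImageVolume):
        self.img = img
        self.grid = img.grid
        gx, gy, gz = np.gradient(img.data, *img.spacing)
        self._grad = (gx, gy, gz)

    def sample(self, points: np.ndarray, with_grad: bool = True):
        ijk = self.grid.to_index(points).T
        vals = map_coordinates(self.img.data, ijk, order=1, mode="constant", cval=0.0)
        if not with_grad:
            return vals, None
        grad = np.stack(
            [map_coordinates(g, ijk, order=1, mode="constant", cval=0.0) for g in self._grad],
            axis=-1,
        )
        return vals, grad


def _bspline_kernel_deriv(s: np.ndarray) -> np.ndarray:
    """Derivative of the centered cubic B-spline."""
    s = np.asarray(s, dtype=float)
    a = np.abs(s)
    out = np.zeros_like(a)
    m1 = a < 1
    m2 = (a >= 1) & (a < 2)
    out[m1] = -2.0 * a[m1] + 1.5 * a[m1] ** 2
    out[m2] = -0.5 * (2.0 - a[m2]) ** 2
    return out * np.sign(s)


class _MattesMI:
    """Parzen-window mutual information and its intensity derivative.

    Zero-order (discrete) window on the fixed intensity, cubic B-spline
    window on the moving intensity; returns the cost ``-MI`` (nats) and
    ``d(-MI)/dM_s`` per sample for chaining with the moving-image gradient.
    """

    def __init__(self, bins: int, intensity_range: tuple[float, float]):
        self.bins = int(bins)
        self.lo, self.hi = intensity_range

    def cost_and_intensity_grad(self, fvals: np.ndarray, mvals: np.ndarray):
        B = self.bins
        S = fvals.size
        eps = 1e-12
        f = np.clip(fvals, self.lo, self.hi)
        m = np.clip(mvals, self.lo, self.hi)
        df = (self.hi - self.lo) / B + eps
        jf = np.minimum((f - self.lo) / df, B - 1).astype(np.int64)
        dm = (self.hi - self.lo) / (B - 4)
        bm = (m - self.lo) / dm + 1.5  # in [1.5, B - 2.5]: all 4 taps in range
        base = np.floor(bm).astype(np.int64) - 1
        taps = base[:, None] + np.arange(4)[None, :]  # (S, 4)
        tw = bspline_kernel(bm[:, None] - taps)
        # joint histogram
        flat = jf[:, None] * B + taps
        P = np.bincount(flat.ravel(), weights=tw.ravel(), minlength=B * B).reshape(B, B) / S
        pf = P.sum(axis=1)
        pm = P.sum(axis=0)
        nz = P > 0
        mi = float(np.sum(P[nz] * np.log(P[nz] / (np.outer(pf, pm)[nz] + eps))))
        # d MI / d bm_s  =  sum_taps beta'(bm - j) * log(P(jf, j) / pm(j))
        L = np.log(np.maximum(P, eps) / np.maximum(pm, eps)[None, :])
        dW = _bspline_kernel_deriv(bm[:, None] - taps)
        dmi_dbm = np.sum(dW * L[jf[:, None], taps], axis=1) / S
        # cost = -MI; d cost / d M_s
        dcost_dm = -dmi_dbm / dm
        return -mi, dcost_dm


def _gain(k: int, schedule: tuple[float, float, float]) -> float:
    a, A, alpha = schedule
    return a / (A + k) ** alpha


@dataclass
class _StageTrace:
    mode: str
    stage: str
    level: int
    cost: list = field(default_factory=list)


def _sample_points(rng: np.random.Generator, grid: Grid, n: int) -> np.ndarray:
    """Uniform continuous samples over the grid's physical box."""
    idx = rng.uniform(low=[0.0, 0.0, 0.0], high=np.asarray(grid.shape, dtype=float) - 1.0, size=(n, 3))
    return grid.to_physical(idx)


def _affine_scales(grid: Grid) -> np.ndarray:
    """Per-parameter scales making one scaled unit worth about one mm of
    displacement: rotations and scale are weighted by the image half-extent."""
    r = float(np.linalg.norm(grid.extent_mm()) / 2.0)
    r = max(r, 1.0)
    return np.array([1.0, 1.0, 1.0, r, r, r, r])


class _StepNormalizer:
    """Turns raw stochastic gradients into bounded descent steps.

    The gradient is smoothed with an exponential average (momentum 0.9,
    bias-corrected) to suppress sampling noise — without it a near-aligned
    group random-walks away from its optimum, because a normalized step at
    zero expected gradient still moves at full gain.  The smoothed gradient
    is scaled by the running maximum of its magnitude over the stage, so
    steps are at most ``gain`` (mm-equivalent) and decay to zero as the
    optimum is approached.
    """

    def __init__(self, beta: float = 0.9) -> None:
        self.beta = beta
        self.gmax = 0.0
        self.avg: np.ndarray | None = None
        self.k = 0

    def step(self, g: np.ndarray, gain: float) -> np.ndarray:
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite registration gradient")
        if self.avg is None:
            self.avg = np.zeros_like(g)
        self.avg = self.beta * self.avg + (1.0 - self.beta) * g
        self.k += 1
        sm = self.avg / (1.0 - self.beta**self.k)
        m = float(np.max(np.abs(sm)))
        self.gmax = max(self.gmax, m)
        if self.gmax == 0:
            return np.zeros_like(g)
        return gain * sm / self.gmax


# ---------------------------------------------------------------------------
# pairwise registration
# ---------------------------------------------------------------------------

def register_pairwise(
    fixed: ImageVolume,
    moving: ImageVolume,
    cfg: RegistrationConfig,
    history: list | None = None,
) -> CompositeTransform:
    """Register ``moving`` to ``fixed`` by maximizing mutual information.

    Hierarchical: a seven-parameter affine stage (translation, ZYX rotation,
    isotropic scale about the fixed-image centre) followed by a cubic
    B-spline stage on a ``cfg.grid_spacing_mm`` lattice, both multi-resolution
    and optimized by stochastic gradient descent on ``-MI`` with
    ``cfg.samples_per_iteration`` random points per step.

    Returns the transform mapping fixed-space points into moving space.
    Append per-stage objective traces to ``history`` if given.
    """
    fixed_n = normalize_intensity(fixed, cfg.intensity_range)
    moving_n = normalize_intensity(moving, cfg.intensity_range)
    fpyr = _pyramid(fixed_n, cfg.n_resolutions)
    mpyr = _pyramid(moving_n, cfg.n_resolutions)
    metric = _MattesMI(cfg.mi_bins, cfg.intensity_range)
    rng = np.random.default_rng(cfg.seed)
    center = fixed.grid.center()
    scales = _affine_scales(fixed.grid)

    # ---- affine stage ----
    p = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0])
    for level in range(cfg.n_resolutions):
        fimg, mov = fpyr[level], _MovingImage(mpyr[level])
        trace = _StageTrace("pairwise", "affine", level)
        p = _optimize_affine_mi(p, center, scales, fimg, mov, metric, cfg, rng, trace)
        if history is not None:
            history.append(trace)
    affine = AffineTransform.from_parameters(p, center)

    # ---- B-spline stage ----
    bspl = _make_lattice_for_affines(fixed.grid, [affine], cfg.grid_spacing_mm)
    for level in range(cfg.n_resolutions):
        fimg, mov = fpyr[level], _MovingImage(mpyr[level])
        trace = _StageTrace("pairwise", "bspline", level)
        _optimize_bspline_mi(bspl, affine, fimg, mov, metric, cfg, rng, trace)
        if history is not None:
            history.append(trace)
    return CompositeTransform([affine, bspl])


def _optimize_affine_mi(p, center, scales, fimg, mov, metric, cfg, rng, trace):
    n_iter = cfg.affine_iterations_per_resolution
    avg_from = max(1, int(0.75 * n_iter))
    accum = np.zeros_like(p)
    n_avg = 0
    norm = _StepNormalizer()
    for k in range(n_iter):
        pts = _sample_points(rng, fimg.grid, cfg.samples_per_iteration)
        fvals = _sample_fixed(fimg, pts)
        t = AffineTransform.from_parameters(p, center)
        y = t.apply(pts)
        mvals, mgrad = mov.sample(y)
        cost, dc_dm = metric.cost_and_intensity_grad(fvals, mvals)
        if not np.isfinite(cost):
            raise FloatingPointError(f"non-finite MI cost at affine iteration {k}")
        trace.cost.append(cost)
        J = t.jacobian_params(pts)  # (S,3,7)
        g = np.einsum("s,sd,sdp->p", dc_dm, mgrad, J)
        # gradient in mm-equivalent units; step back-scaled per parameter
        h = g / scales
        step = norm.step(h, _gain(k, cfg.step_size_schedule))
        p = p - step / scales
        if k >= avg_from:
            accum += p
            n_avg += 1
    return accum / n_avg if n_avg else p


def _sample_fixed(fimg: ImageVolume, pts: np.ndarray) -> np.ndarray:
    ijk = fimg.grid.to_index(pts).T
    return map_coordinates(fimg.data, ijk, order=1, mode="constant", cval=0.0)


def _make_lattice_for_affines(ref: Grid, affines: list[AffineTransform], sigma: float) -> BSplineTransform:
    """One lattice covering the reference box and its image under every
    affine, so that all composite evaluations stay inside full support."""
    lo = np.asarray(ref.origin, dtype=float)
    hi = lo + ref.extent_mm()
    corners = np.array([[a, b, c] for a in (lo[0], hi[0]) for b in (lo[1], hi[1]) for c in (lo[2], hi[2])])
    boxes = [corners] + [t.apply(corners) for t in affines]
    allpts = np.concatenate(boxes)
    return BSplineTransform.for_domain(allpts.min(axis=0), allpts.max(axis=0), sigma)


def _optimize_bspline_mi(bspl, affine, fimg, mov, metric, cfg, rng, trace):
    coef = bspl.coefficients
    shape = coef.shape
    n_iter = cfg.iterations_per_resolution
    ncp = coef[..., 0].size
    avg_from = max(1, int(0.75 * n_iter))
    accum = np.zeros_like(coef)
    n_avg = 0
    norm = _StepNormalizer()
    for k in range(n_iter):
        pts = _sample_points(rng, fimg.grid, cfg.samples_per_iteration)
        fvals = _sample_fixed(fimg, pts)
        z = affine.apply(pts)
        idx, w = bspl.support_terms(z)
        disp = np.einsum("nk,nkd->nd", w, coef.reshape(-1, 3)[idx])
        mvals, mgrad = mov.sample(z + disp)
        cost, dc_dm = metric.cost_and_intensity_grad(fvals, mvals)
        if not np.isfinite(cost):
            raise FloatingPointError(f"non-finite MI cost at B-spline iteration {k}")
        trace.cost.append(cost)
        g = _scatter_coef_grad(idx, w, dc_dm, mgrad, ncp)
        step = norm.step(g, _gain(k, cfg.step_size_schedule))
        coef = coef - step.reshape(shape)
        if k >= avg_from:
            accum += coef
            n_avg += 1
    bspl.coefficients = accum / n_avg if n_avg else coef


def _scatter_coef_grad(idx, w, dc_dm, mgrad, ncp):
    """Accumulate d cost / d coefficients, shape (ncp, 3)."""
    g = np.empty((ncp, 3))
    flat = idx.ravel()
    for d in range(3):
        contrib = (w * (dc_dm * mgrad[:, d])[:, None]).ravel()
        g[:, d] = np.bincount(flat, weights=contrib, minlength=ncp)
    return g


# ---------------------------------------------------------------------------
# joint (groupwise) registration
# ---------------------------------------------------------------------------

def register_joint(
    target: ImageVolume,
    atlases: list[ImageVolume],
    cfg: RegistrationConfig,
    history: list | None = None,
) -> tuple[GroupTransformEnsemble, ImageVolume]:
    """Register the target and all atlases jointly in one optimization.

    The cost is the intensity variance across the warped group (target plus
    ``N`` atlases), whose minimizer aligns every member to a common
    mean-shape coordinate frame.  The hierarchy (groupwise affine, then
    groupwise B-spline), pyramid, and optimizer mirror
    :func:`register_pairwise`.  After every iteration the group-mean
    parameter update is subtracted (zero-mean gauge), removing the common
    drift the metric cannot see.

    Returns the ensemble of transforms (index 0 = target) and the mean-shape
    image on the reference grid (the target's geometry).
    """
    if len(atlases) < 2:
        raise ValueError("joint registration needs at least 2 atlases")
    imgs = [normalize_intensity(target, cfg.intensity_range)] + [
        normalize_intensity(a, cfg.intensity_range) for a in atlases
    ]
    M = len(imgs)
    ref = target.grid
    pyramids = [_pyramid(im, cfg.n_resolutions) for im in imgs]
    ref_pyr = _pyramid(ImageVolume(np.zeros(ref.shape), ref.spacing, ref.origin), cfg.n_resolutions)
    rng = np.random.default_rng(cfg.seed)
    center = ref.center()
    scales = _affine_scales(ref)

    # ---- groupwise affine ----
    P = np.tile(np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0]), (M, 1))
    for level in range(cfg.n_resolutions):
        movs = [_MovingImage(pyramids[j][level]) for j in range(M)]
        trace = _StageTrace("joint", "affine", level)
        P = _optimize_affine_group(P, center, scales, ref_pyr[level].grid, movs, cfg, rng, trace)
        if history is not None:
            history.append(trace)
    affines = [AffineTransform.from_parameters(P[j], center) for j in range(M)]

    # ---- groupwise B-spline (one shared lattice geometry) ----
    proto = _make_lattice_for_affines(ref, affines, cfg.grid_spacing_mm)
    coefs = np.zeros((M, *proto.coefficients.shape))
    for level in range(cfg.n_resolutions):
        movs = [_MovingImage(pyramids[j][level]) for j in range(M)]
        trace = _StageTrace("joint", "bspline", level)
        coefs = _optimize_bspline_group(coefs, proto, affines, ref_pyr[level].grid, movs, cfg, rng, trace)
        if history is not None:
            history.append(trace)

    transforms = []
    for j in range(M):
        bspl = BSplineTransform(proto.grid_origin.copy(), proto.grid_spacing.copy(), coefs[j].copy())
        transforms.append(CompositeTransform([affines[j], bspl]))
    ensemble = GroupTransformEnsemble(transforms, ref)

    from .transforms import resample  # local import to avoid cycle at module load

    warped = [resample(imgs[j], transforms[j], ref, mode="linear") for j in range(M)]
    return ensemble, mean_shape(warped)


def _group_sample_cost(vals: np.ndarray) -> tuple[float, np.ndarray]:
    """Variance cost over a (M, S) sample matrix and d cost / d vals."""
    mean = vals.mean(axis=0)
    dev = vals - mean
    S = vals.shape[1]
    cost = float(np.sum(dev * dev) / S)
    # the mean's dependence cancels: sum_j dev_j = 0
    grad = 2.0 * dev / S
    return cost, grad


def _optimize_affine_group(P, center, scales, ref_grid, movs, cfg, rng, trace):
    M = P.shape[0]
    n_iter = cfg.affine_iterations_per_resolution
    avg_from = max(1, int(0.75 * n_iter))
    accum = np.zeros_like(P)
    n_avg = 0
    norm = _StepNormalizer()
    for k in range(n_iter):
        pts = _sample_points(rng, ref_grid, cfg.samples_per_iteration)
        vals = np.empty((M, pts.shape[0]))
        grads = []
        Js = []
        for j in range(M):
            t = AffineTransform.from_parameters(P[j], center)
            y = t.apply(pts)
            v, g = movs[j].sample(y)
            vals[j] = v
            grads.append(g)
            Js.append(t.jacobian_params(pts))
        cost, dvals = _group_sample_cost(vals)
        if not np.isfinite(cost):
            raise FloatingPointError(f"non-finite group cost at affine iteration {k}")
        trace.cost.append(cost)
        G = np.stack(
            [np.einsum("s,sd,sdp->p", dvals[j], grads[j], Js[j]) / scales for j in range(M)]
        )
        steps = norm.step(G, _gain(k, cfg.step_size_schedule))
        steps -= steps.mean(axis=0)  # zero-mean gauge
        P = P - steps / scales
        if k >= avg_from:
            accum += P
            n_avg += 1
    return accum / n_avg if n_avg else P


def _optimize_bspline_group(coefs, proto, affines, ref_grid, movs, cfg, rng, trace):
    M = coefs.shape[0]
    cshape = coefs.shape[1:]
    ncp = coefs[0, ..., 0].size
    n_iter = cfg.iterations_per_resolution
    avg_from = max(1, int(0.75 * n_iter))
    accum = np.zeros_like(coefs)
    n_avg = 0
    norm = _StepNormalizer()
    lat = BSplineTransform(proto.grid_origin, proto.grid_spacing, np.zeros(cshape))
    for k in range(n_iter):
        pts = _sample_points(rng, ref_grid, cfg.samples_per_iteration)
        vals = np.empty((M, pts.shape[0]))
        grads = []
        supports = []
        for j in range(M):
            z = affines[j].apply(pts)
            idx, w = lat.support_terms(z)
            disp = np.einsum("nk,nkd->nd", w, coefs[j].reshape(-1, 3)[idx])
            v, g = movs[j].sample(z + disp)
            vals[j] = v
            grads.append(g)
            supports.append((idx, w))
        cost, dvals = _group_sample_cost(vals)
        if not np.isfinite(cost):
            raise FloatingPointError(f"non-finite group cost at B-spline iteration {k}")
        trace.cost.append(cost)
        G = np.stack(
            [_scatter_coef_grad(supports[j][0], supports[j][1], dvals[j], grads[j], ncp) for j in range(M)]
        )
        steps = norm.step(G, _gain(k, cfg.step_size_schedule))
        steps -= steps.mean(axis=0)  # zero-mean gauge
        coefs = coefs - steps.reshape(coefs.shape)
        if k >= avg_from:
            accum += coefs
            n_avg += 1
    return accum / n_avg if n_avg else coefs
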