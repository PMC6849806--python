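"""Affine / B-spline transform models, resampling, and inversion."""

import numpy as np
import pytest

from jointatlas.transforms import (
    AffineTransform,
    BSplineTransform,
    CompositeTransform,
    IdentityTransform,
    bspline_kernel,
    invert_transform,
    load_transform,
    resample,
    save_transform,
)
from jointatlas.volumes import Grid, ImageVolume, LabelVolume

from conftest import toy_image, toy_labels


class TestAffine:
    @pytest.mark.parametrize(
        "kwargs,x,expected",
        [
            ({}, (10, 20, 30), (10, 20, 30)),  # identity parameters
            ({"translation": (1, 2, 3)}, (0, 0, 0), (1, 2, 3)),  # pure translation
            ({"scale": 2.0}, (1, 1, 1), (2, 2, 2)),  # isotropic scale about origin
        ],
    )
    def test_point_mapping(self, kwargs, x, expected):
        t = AffineTransform(**kwargs)
        np.testing.assert_allclose(t.apply(np.array(x, dtype=float)), expected, atol=1e-12)

    def test_scale_about_matrix_evaluation(self):
        """Direct matrix evaluation: x -> c + s R (x - c) + t."""
        t = AffineTransform(translation=(1, 0, -2), rotation=(0.1, -0.2, 0.3), scale=1.5, center=(5, 5, 5))
        x = np.array([2.0, -1.0, 7.0])
        expected = np.array(t.center) + t.matrix() @ (x - t.center) + t.translation
        np.testing.assert_allclose(t.apply(x), expected, atol=1e-12)

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            AffineTransform(scale=0.0)

    def test_composition_matches_sequential_application(self, rng):
        a = AffineTransform(translation=(1, 2, 3), rotation=(0.1, 0.2, 0.3), scale=1.1, center=(4, 4, 4))
        b = AffineTransform(translation=(-2, 0, 1), rotation=(0.0, -0.1, 0.05), scale=0.9)
        comp = CompositeTransform([a, b])
        pts = rng.normal(0, 10, (20, 3))
        np.testing.assert_allclose(comp.apply(pts), b.apply(a.apply(pts)), atol=1e-12)

    def test_empty_composite_is_identity(self, rng):
        pts = rng.normal(0, 10, (5, 3))
        np.testing.assert_array_equal(CompositeTransform([]).apply(pts), pts)


class TestBSpline:
    def make(self, rng=None, sigma=10.0):
        t = BSplineTransform.for_domain([0, 0, 0], [50, 50, 50], sigma)
        if rng is not None:
            t.coefficients = rng.normal(0, 2.0, size=t.coefficients.shape)
        return t

    def test_zero_coefficients_identity(self, rng):
        t = self.make()
        pts = rng.uniform(0, 50, (30, 3))
        np.testing.assert_allclose(t.displacement(pts), 0.0, atol=1e-14)

    def test_partition_of_unity(self, rng):
        """Uniform coefficients act as a pure translation at every interior
        point: the tensor-product weights sum to one."""
        t = self.make()
        c = np.array([5.0, -3.0, 2.5])
        t.coefficients[...] = c
        pts = rng.uniform(0, 50, (100, 3))
        disp = t.displacement(pts)
        np.testing.assert_allclose(disp, np.tile(c, (100, 1)), rtol=1e-9)

    def test_matches_brute_force_summation(self, rng):
        """Evaluation from the 4x4x4 support equals summation over ALL
        control points of the tensor-product kernel."""
        t = self.make(rng)
        n = t.coefficients.shape[:3]
        kx, ky, kz = np.meshgrid(*[np.arange(m) for m in n], indexing="ij")
        xk = t.grid_origin + np.stack([kx, ky, kz], -1) * t.grid_spacing
        pts = rng.uniform(5, 45, (20, 3))
        # single nonzero coefficient at a lattice point, evaluated there
        t_single = self.make()
        t_single.coefficients[6, 6, 6] = (1.5, -0.5, 2.0)
        for tr, sample in ((t, pts), (t_single, [t_single.grid_origin + 6 * t_single.grid_spacing])):
            for p in sample:
                s = (np.asarray(p) - xk) / tr.grid_spacing
                w = bspline_kernel(s[..., 0]) * bspline_kernel(s[..., 1]) * bspline_kernel(s[..., 2])
                brute = np.einsum("ijk,ijkd->d", w, tr.coefficients)
                np.testing.assert_allclose(tr.displacement(np.asarray(p, dtype=float)), brute, atol=1e-9)

    def test_locality_of_control_points(self, rng):
        """Perturbing one control point changes displacements only inside its
        4-spacing support box."""
        t = self.make(rng)
        t2 = BSplineTransform(t.grid_origin, t.grid_spacing, t.coefficients.copy())
        k = np.array([5, 5, 5])
        t2.coefficients[tuple(k)] += (3.0, 0, 0)
        xk = t.grid_origin + k * t.grid_spacing
        pts = rng.uniform(0, 50, (300, 3))
        d = np.abs(t.displacement(pts) - t2.displacement(pts)).max(axis=1)
        outside = np.any(np.abs(pts - xk) >= 2 * t.grid_spacing, axis=1)
        assert np.all(d[outside] == 0)
        inside = ~outside
        if inside.any():
            assert d[inside].max() > 0

    def test_out_of_support_raises_with_coordinate(self):
        t = self.make()
        bad = np.array([200.0, 25.0, 25.0])
        with pytest.raises(ValueError, match=r"200"):
            t.displacement(bad)


class TestResample:
    def test_identity_is_copy(self, rng):
        img = toy_image(rng.random((6, 7, 8)) * 100, spacing=(1.0, 2.0, 0.5))
        out = resample(img, IdentityTransform())
        np.testing.assert_allclose(out.data, img.data, atol=1e-12)

    def test_one_voxel_shift_is_exact(self, rng):
        img = toy_image(rng.random((8, 6, 6)) * 10, spacing=(1.5, 1.0, 1.0))
        t = AffineTransform(translation=(1.5, 0, 0))
        out = resample(img, t)
        np.testing.assert_allclose(out.data[:-1], img.data[1:], atol=1e-12)

    def test_half_voxel_shift_linear_interpolation(self):
        data = np.zeros((4, 1, 1))
        data[2:] = 10.0
        img = toy_image(data)
        out = resample(img, AffineTransform(translation=(0.5, 0, 0)))
        assert out.data[1, 0, 0] == pytest.approx(5.0)

    def test_nearest_mandatory_for_labels(self):
        lab = toy_labels(np.ones((3, 3, 3), dtype=int))
        with pytest.raises(ValueError, match="nearest"):
            resample(lab, IdentityTransform(), mode="linear")

    def test_label_resampling_preserves_label_set(self, rng):
        lab = toy_labels(rng.integers(0, 3, (8, 8, 8)))
        out = resample(lab, AffineTransform(translation=(0.3, -0.2, 0.7)), mode="nearest")
        assert set(np.unique(out.data)) <= set(np.unique(lab.data)) | {0}

    def test_roundtrip_through_inverse_small_error(self, rng):
        """resample(resample(img, t), t^-1) ~ img in the interior."""
        x = np.arange(24) * 2.0
        xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
        img = toy_image(np.sin(xx / 8) * np.cos(yy / 9) * np.sin(zz / 7) * 50 + 50, spacing=(2, 2, 2))
        t = BSplineTransform.for_grid(img.grid, 12.0)
        t.coefficients = rng.normal(0, 1.2, t.coefficients.shape)
        inv = invert_transform(t, img.grid, tol=0.1)
        back = resample(resample(img, t), inv)
        core = (slice(4, -4),) * 3
        mae = np.abs(back.data[core] - img.data[core]).mean()
        # bound: interpolation error of one resampling on this smooth image
        shifted = resample(img, AffineTransform(translation=(1.0, 1.0, 1.0)))
        unshifted = resample(shifted, AffineTransform(translation=(-1.0, -1.0, -1.0)))
        bound = 4 * np.abs(unshifted.data[core] - img.data[core]).mean()
        assert mae < bound


class TestInversion:
    def test_identity_inverts_to_identity(self):
        g = Grid((10, 10, 10), (2, 2, 2))
        inv = invert_transform(IdentityTransform(), g, tol=1e-6)
        pts = g.physical_points().reshape(-1, 3)
        np.testing.assert_allclose(inv.apply(pts), pts, atol=1e-9)

    def test_translation_inverts_to_negative(self):
        g = Grid((10, 10, 10), (2, 2, 2))
        inv = invert_transform(AffineTransform(translation=(3, -1, 2)), g, tol=1e-3)
        pts = g.physical_points().reshape(-1, 3)[::7]
        np.testing.assert_allclose(inv.apply(pts) - pts, np.tile([-3, 1, -2], (len(pts), 1)), atol=1e-3)

    def test_smooth_warp_roundtrip_residual(self, rng):
        g = Grid((20, 20, 20), (2.5, 2.5, 2.5))
        t = BSplineTransform.for_grid(g, 12.0)
        t.coefficients = np.clip(rng.normal(0, 2.0, t.coefficients.shape), -4.8, 4.8)  # <= 0.4 sigma
        inv = invert_transform(t, g, tol=0.1, max_iter=50)
        pts = g.physical_points()[::2, ::2, ::2].reshape(-1, 3)
        fwd = t.apply(pts)
        lo, hi = np.zeros(3), np.asarray(g.extent_mm())
        keep = np.all((fwd >= lo) & (fwd <= hi), axis=1)
        res = np.linalg.norm(inv.apply(fwd[keep]) - pts[keep], axis=1)
        assert res.max() <= 0.1

    def test_failure_reports_residual(self):
        g = Grid((8, 8, 8), (4, 4, 4))
        t = BSplineTransform.for_grid(g, 8.0)
        t.coefficients[...] = 0.0
        t.coefficients[3:6, 3:6, 3:6] = 12.0  # heavily folding warp
        with pytest.raises(RuntimeError, match="residual"):
            invert_transform(t, g, tol=0.01, max_iter=3)


class TestSerialization:
    def test_json_roundtrip(self, tmp_path, rng):
        b = BSplineTransform.for_domain([0, 0, 0], [30, 30, 30], 10.0)
        b.coefficients = rng.normal(0, 1, b.coefficients.shape)
        t = CompositeTransform([AffineTransform(translation=(1, 2, 3), rotation=(0.1, 0, 0), scale=1.2), b])
        path = tmp_path / "t.json"
        save_transform(t, path)
        t2 = load_transform(path)
        pts = rng.uniform(5, 25, (20, 3))
        np.testing.assert_allclose(t2.apply(pts), t.apply(pts), atol=1e-12)
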