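"""Similarity metrics and the registration framework."""

import dataclasses

import numpy as np
import pytest

from jointatlas.config import RegistrationConfig
from jointatlas.registration import (
    group_variance,
    mean_shape,
    mutual_information,
    normalize_intensity,
    register_joint,
    register_pairwise,
)
from jointatlas.transforms import AffineTransform, resample
from jointatlas.volumes import ImageVolume

from conftest import toy_image


class TestNormalizeIntensity:
    def test_linear_map_of_extrema(self):
        img = toy_image(np.array([[[0.0, 50.0, 100.0]]]))
        out = normalize_intensity(img, (0, 255))
        np.testing.assert_allclose(out.data, [[[0.0, 127.5, 255.0]]])

    def test_full_range_is_fixed_point(self, rng):
        data = rng.random((4, 4, 4)) * 255
        data.flat[0], data.flat[-1] = 0.0, 255.0
        img = toy_image(data)
        np.testing.assert_allclose(normalize_intensity(img).data, img.data)

    def test_constant_image_maps_to_low(self):
        out = normalize_intensity(toy_image(np.full((3, 3, 3), 42.0)), (0, 255))
        np.testing.assert_array_equal(out.data, 0.0)


class TestMutualInformation:
    def test_self_information_is_entropy(self, rng):
        data = rng.random((16, 16, 16)) * 255
        img = toy_image(data)
        bins = 32
        h, _ = np.histogram(data.ravel(), bins=bins)
        p = h / h.sum()
        entropy = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert mutual_information(img, img, bins) == pytest.approx(entropy, rel=1e-12)

    def test_independent_noise_near_zero(self, rng):
        a = toy_image(rng.random((64, 64, 64)))
        b = toy_image(rng.random((64, 64, 64)))
        assert mutual_information(a, b, 32) < 0.05

    def test_two_voxel_case_one_bit(self):
        a = toy_image(np.array([[[0.0, 255.0]]]))
        b = toy_image(np.array([[[255.0, 0.0]]]))
        assert mutual_information(a, b, bins=2) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a = toy_image(rng.random((10, 10, 10)))
        b = toy_image(rng.random((10, 10, 10)) ** 2)
        assert mutual_information(a, b, 16) == pytest.approx(mutual_information(b, a, 16), rel=1e-12)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError):
            mutual_information(toy_image(np.zeros((2, 2, 2))), toy_image(np.zeros((3, 2, 2))))


class TestGroupVarianceAndMeanShape:
    def test_identical_images_zero_variance(self, rng):
        img = toy_image(rng.random((4, 4, 4)))
        assert group_variance([img, img.copy(), img.copy()]) == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(mean_shape([img, img.copy()]).data, img.data)

    def test_one_voxel_group_hand_computed(self):
        imgs = [toy_image(np.full((1, 1, 1), v)) for v in (0.0, 2.0)]
        assert group_variance(imgs) == pytest.approx(2.0)
        assert mean_shape(imgs).data[0, 0, 0] == pytest.approx(1.0)
        imgs3 = [toy_image(np.full((1, 1, 1), v)) for v in (0.0, 3.0, 6.0)]
        assert mean_shape(imgs3).data[0, 0, 0] == pytest.approx(3.0)

    def test_constant_shift_invariance(self, rng):
        imgs = [toy_image(rng.random((3, 3, 3))) for _ in range(4)]
        shifted = [toy_image(im.data + 7.5) for im in imgs]
        assert group_variance(shifted) == pytest.approx(group_variance(imgs))

    def test_permutation_invariance(self, rng):
        imgs = [toy_image(rng.random((3, 3, 3))) for _ in range(5)]
        perm = [imgs[i] for i in (3, 0, 4, 1, 2)]
        assert group_variance(perm) == pytest.approx(group_variance(imgs), rel=1e-12)
        np.testing.assert_allclose(mean_shape(perm).data, mean_shape(imgs).data)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mean_shape([])


class TestConfig:
    def test_shared_fields_consumed_by_both_modes(self):
        """Both registration modes take the same configuration object; the
        schema has no mode-specific field."""
        fields = {f.name for f in dataclasses.fields(RegistrationConfig)}
        assert {
            "n_resolutions",
            "iterations_per_resolution",
            "grid_spacing_mm",
            "samples_per_iteration",
            "step_size_schedule",
            "seed",
            "intensity_range",
            "mi_bins",
        } <= fields

    def test_validation(self):
        with pytest.raises(ValueError):
            RegistrationConfig(n_resolutions=0)
        with pytest.raises(ValueError):
            RegistrationConfig(intensity_range=(10, 10))

    def test_yaml_roundtrip(self, tmp_path):
        cfg = RegistrationConfig(seed=7, grid_spacing_mm=12.5)
        cfg.save(tmp_path / "cfg.yaml")
        assert RegistrationConfig.load(tmp_path / "cfg.yaml") == cfg


FAST = dict(
    n_resolutions=2,
    affine_iterations_per_resolution=150,
    iterations_per_resolution=150,
    samples_per_iteration=1024,
)


class TestRegisterPairwise:
    def test_self_registration_near_identity(self, noisy_template):
        fixed = noisy_template.image
        cfg = RegistrationConfig(seed=3, **FAST)
        t = register_pairwise(fixed, fixed, cfg)
        pts = fixed.grid.physical_points()[::6, ::6, ::4].reshape(-1, 3)
        disp = np.linalg.norm(t.apply(pts) - pts, axis=1)
        assert disp.mean() <= 0.2 * min(fixed.spacing)

    def test_translation_recovery(self, noisy_template):
        fixed = noisy_template.image
        tau = np.array([4.0, -3.0, 2.0])
        moving = resample(fixed, AffineTransform(translation=-tau), fixed.grid, mode="linear")
        cfg = RegistrationConfig(seed=3, iterations_per_resolution=0, n_resolutions=3,
                                 affine_iterations_per_resolution=200)
        t = register_pairwise(fixed, moving, cfg)
        np.testing.assert_allclose(t.transforms[0].translation, tau, atol=0.5)

    def test_objective_trace_decreases_smoothed(self, noisy_template):
        fixed = noisy_template.image
        moving = resample(fixed, AffineTransform(translation=(-3, 2, -1)), fixed.grid, mode="linear")
        hist = []
        register_pairwise(fixed, moving, RegistrationConfig(seed=5, **FAST), history=hist)
        for tr in hist:
            c = np.asarray(tr.cost)
            w = np.convolve(c, np.ones(50) / 50, mode="valid")
            span = max(np.ptp(w), abs(w[0]), 1e-9)
            assert np.all(np.diff(w) <= 0.02 * span), f"{tr.stage} level {tr.level} not decreasing"

    def test_determinism_bitwise(self, noisy_template):
        fixed = noisy_template.image
        moving = resample(fixed, AffineTransform(translation=(2, 1, -1)), fixed.grid, mode="linear")
        cfg = RegistrationConfig(seed=9, n_resolutions=2, affine_iterations_per_resolution=40,
                                 iterations_per_resolution=40, samples_per_iteration=512)
        t1 = register_pairwise(fixed, moving, cfg)
        t2 = register_pairwise(fixed, moving, cfg)
        np.testing.assert_array_equal(t1.transforms[0].parameters(), t2.transforms[0].parameters())
        np.testing.assert_array_equal(t1.transforms[1].coefficients, t2.transforms[1].coefficients)


class TestRegisterJoint:
    def test_requires_two_atlases(self, noisy_template):
        with pytest.raises(ValueError):
            register_joint(noisy_template.image, [noisy_template.image], RegistrationConfig())

    def test_identical_inputs_stay_near_identity(self, clean_template):
        img = clean_template.image
        cfg = RegistrationConfig(seed=4, n_resolutions=2, affine_iterations_per_resolution=80,
                                 iterations_per_resolution=80, samples_per_iteration=1024)
        ens, mean_img = register_joint(img, [img.copy(), img.copy()], cfg)
        pts = img.grid.physical_points()[::6, ::6, ::4].reshape(-1, 3)
        for t in ens.transforms:
            disp = np.linalg.norm(t.apply(pts) - pts, axis=1)
            assert disp.mean() <= 0.2 * min(img.spacing)
        # variance of the warped identical group stays ~ 0
        warped = [resample(normalize_intensity(img), t, img.grid, mode="linear") for t in ens.transforms]
        assert group_variance(warped) <= 1e-2 * group_variance([normalize_intensity(img)] * 3) + 5.0
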