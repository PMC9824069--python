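"""Simulator invariants: lattice geometry, masks, determinism."""

import numpy as np
import pytest
from scipy import ndimage

from debundle import bundlesim
from debundle.bundlesim import BundleSpec


class TestReference:
    def test_deterministic_for_fixed_seed(self):
        spec = BundleSpec(image_size=(96, 96), seed=11)
        a = bundlesim.generate_reference(spec)
        b = bundlesim.generate_reference(spec)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        np.testing.assert_array_equal(a.core_centers, b.core_centers)

    def test_unjittered_cores_peak_at_lattice_sites(self):
        spec = BundleSpec(image_size=(64, 64), core_pitch=6.0,
                          jitter_sigma=0.0, intensity_jitter=0.0, seed=0)
        ref = bundlesim.generate_reference(spec)
        peak = ref.pixels.max()
        # the field maximum sits on a core; every core carries the same
        # (sub-pixel-sampled) peak value
        sampled = ndimage.map_coordinates(ref.pixels, ref.core_centers.T,
                                          order=3)
        assert sampled.min() > 0.97 * peak
        top = np.unravel_index(np.argmax(ref.pixels), ref.pixels.shape)
        dist = np.hypot(*(ref.core_centers - np.asarray(top)).T).min()
        assert dist < 1.0

    def test_fov_mask_forces_outside_to_zero(self):
        spec = BundleSpec(image_size=(64, 64), fov_radius=10.0, seed=1)
        ref = bundlesim.generate_reference(spec)
        yy, xx = np.mgrid[:64, :64]
        outside = np.hypot(yy - 31.5, xx - 31.5) > 10.0
        assert np.all(ref.pixels[outside] == 0.0)

    def test_core_count_matches_hexagonal_packing_density(self):
        spec = BundleSpec(image_size=(1024, 1024), core_pitch=5.5, seed=3)
        ref = bundlesim.generate_reference(spec)
        radius = spec.resolved_fov_radius
        expected = np.pi * radius**2 / (spec.core_pitch**2 * np.sqrt(3) / 2)
        assert abs(len(ref.core_centers) - expected) < 0.10 * expected

    def test_unjittered_lattice_is_sixfold_symmetric(self):
        spec = BundleSpec(image_size=(129, 129), jitter_sigma=0.0,
                          intensity_jitter=0.0, fov_radius=58.0, seed=0)
        ref = bundlesim.generate_reference(spec)
        rotated = ndimage.rotate(ref.pixels, 60.0, reshape=False, order=3,
                                 mode="constant")
        diff = np.abs(rotated - ref.pixels).mean()
        assert diff < 0.02 * ref.pixels.max()

    def test_merged_cores_flagged(self):
        spec = BundleSpec(image_size=(64, 64), core_pitch=2.0, core_sigma=1.5)
        with pytest.warns(UserWarning, match="merge"):
            bundlesim.generate_reference(spec)

    @pytest.mark.parametrize("field,value", [
        ("core_pitch", -1.0), ("core_sigma", 0.0),
        ("intensity_jitter", 1.0), ("fov_radius", 200.0),
    ])
    def test_invalid_spec_rejected(self, field, value):
        with pytest.raises(ValueError):
            BundleSpec(image_size=(64, 64), **{field: value})


class TestBarTarget:
    def test_contrast_spans_full_range(self):
        image, _ = bundlesim.generate_bar_target((64, 64), bar_period=8,
                                                 contrast=1.0)
        assert image.max() == 1.0 and image.min() == 0.0

    def test_profile_period_matches_bar_period(self):
        image, _ = bundlesim.generate_bar_target((64, 64), bar_period=8)
        profile = image[:32].mean(axis=1)
        np.testing.assert_allclose(profile[:-8], profile[8:])
        assert profile.max() != profile.min()

    def test_flat_region_has_zero_variance(self):
        image, regions = bundlesim.generate_bar_target((128, 128))
        assert regions["flat"].extract(image).var() == 0.0

    def test_lines_region_sees_both_levels(self):
        image, regions = bundlesim.generate_bar_target((128, 128),
                                                       contrast=0.75)
        sub = regions["lines"].extract(image)
        assert sub.max() == 1.0 and sub.min() == 0.25

    def test_vertical_orientation_transposes(self):
        hor, hreg = bundlesim.generate_bar_target((96, 96), orientation="horizontal")
        ver, vreg = bundlesim.generate_bar_target((96, 96), orientation="vertical")
        np.testing.assert_array_equal(ver, hor.T)
        assert vreg["lines"].line_axis == 1

    def test_regions_inside_central_fov(self):
        size = 256
        _, regions = bundlesim.generate_bar_target((size, size))
        radius = size / 2 - 1
        for spec in regions.values():
            corners = [(r, c) for r in spec.rows for c in spec.cols]
            for r, c in corners:
                assert np.hypot(r - (size - 1) / 2, c - (size - 1) / 2) < radius


class TestTexture:
    def test_deterministic_for_fixed_seed(self):
        a = bundlesim.generate_texture((64, 64), 3.0, seed=5)
        b = bundlesim.generate_texture((64, 64), 3.0, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_bounded_to_unit_interval(self):
        t = bundlesim.generate_texture((64, 64), 1.0, seed=0)
        assert t.min() >= 0.0 and t.max() <= 1.0

    def test_long_correlation_flattens_field(self):
        # fixed-gain normalization: far-supra-image correlation length must
        # give lower variance than unit correlation length, seed by seed
        var_long = np.mean([
            bundlesim.generate_texture((64, 64), 200.0, seed=s).var()
            for s in range(20)])
        var_short = np.mean([
            bundlesim.generate_texture((64, 64), 1.0, seed=s).var()
            for s in range(20)])
        assert var_long < var_short


def test_outputs_are_finite(small_ref):
    for arr in (small_ref.pixels,
                bundlesim.generate_bar_target((64, 64))[0],
                bundlesim.generate_texture((64, 64), 4.0, seed=2)):
        assert np.all(np.isfinite(arr))
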