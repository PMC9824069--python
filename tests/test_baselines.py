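"""Baseline restorers: filters, core detection, barycentric interpolation."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from debundle import baselines
from debundle.baselines import CoreMap


class TestMedian:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 0.4)
        np.testing.assert_array_equal(baselines.median_restore(img), img)

    def test_isolated_impulse_removed(self):
        img = np.zeros((21, 21))
        img[10, 10] = 1.0
        np.testing.assert_array_equal(baselines.median_restore(img, 7),
                                      np.zeros((21, 21)))

    def test_matches_brute_force_sorted_median(self):
        rng = np.random.default_rng(0)
        img = rng.random((9, 9))
        got = baselines.median_restore(img, 3)
        padded = np.pad(img, 1, mode="edge")
        for i in range(9):
            for j in range(9):
                window = np.sort(padded[i : i + 3, j : j + 3].ravel())
                assert got[i, j] == window[4]

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            baselines.median_restore(np.zeros((8, 8)), size=4)


class TestGaussian:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 0.7)
        np.testing.assert_allclose(baselines.gaussian_restore(img), img)

    def test_kernel_normalized(self):
        assert baselines.gaussian_kernel(3.0).sum() == pytest.approx(1.0,
                                                                     abs=1e-9)

    def test_impulse_response_is_sampled_gaussian(self):
        sigma = 1.5
        radius = int(np.ceil(3 * sigma))
        n = 4 * radius + 1
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 1.0
        out = baselines.gaussian_restore(img, sigma)
        kernel = baselines.gaussian_kernel(sigma)
        sub = out[n // 2 - radius : n // 2 + radius + 1,
                  n // 2 - radius : n // 2 + radius + 1]
        np.testing.assert_allclose(sub, kernel, atol=1e-12)

    @pytest.mark.parametrize("restore", [baselines.median_restore,
                                         baselines.gaussian_restore])
    def test_filters_commute_with_intensity_scaling(self, restore):
        rng = np.random.default_rng(1)
        img = rng.random((16, 16))
        np.testing.assert_allclose(restore(3.0 * img), 3.0 * restore(img),
                                   atol=1e-10)


class TestDetectCores:
    def test_recovers_simulated_unjittered_centers(self, clean_ref):
        cores = baselines.detect_cores(clean_ref)
        truth = clean_ref.core_centers
        # score only cores clear of the FOV rim, where bumps are clipped
        c0 = np.asarray(clean_ref.pixels.shape) / 2 - 0.5
        interior = np.hypot(*(truth - c0).T) < 55
        tree = cKDTree(cores.centers)
        dist, _ = tree.query(truth[interior])
        recall = np.mean(dist < 1.0)
        tree_t = cKDTree(truth)
        dist_p, _ = tree_t.query(cores.centers)
        precision = np.mean(dist_p < 1.0)
        assert recall >= 0.95 and precision >= 0.95

    def test_two_separated_bumps(self):
        img = np.zeros((32, 32))
        yy, xx = np.mgrid[:32, :32]
        for cy, cx in [(10, 16), (20, 16)]:
            img += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / 2.0)
        cores = baselines.detect_cores(img, min_distance=3)
        assert len(cores.centers) == 2

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            baselines.detect_cores(np.full((32, 32), 0.5))

    def test_subpixel_refinement_beats_integer_grid(self):
        # a bump centered between pixels should be localized to < 0.5 px
        yy, xx = np.mgrid[:21, :21]
        img = np.exp(-((yy - 10.3) ** 2 + (xx - 9.6) ** 2) / 2.0)
        cores = baselines.detect_cores(img, min_distance=3)
        err = np.hypot(*(cores.centers[0] - np.array([10.3, 9.6])))
        assert err < 0.25


class TestInterpolation:
    @staticmethod
    def grid_cores(h, w, step=6):
        pts = [(float(r), float(c)) for r in range(0, h, step)
               for c in range(0, w, step)]
        return CoreMap(np.asarray(pts))

    def test_constant_core_values_give_constant_interior(self):
        cores = self.grid_cores(30, 30)
        img = np.full((30, 30), 0.42)
        out = baselines.interpolation_restore(img, cores)
        hull = out > 0
        np.testing.assert_allclose(out[hull], 0.42, atol=1e-6)

    def test_linear_ramp_reproduced_exactly(self):
        h = w = 36
        yy, xx = np.mgrid[:h, :w].astype(np.float64)
        ramp = 0.01 * yy + 0.02 * xx + 0.1
        cores = self.grid_cores(h, w)
        out = baselines.interpolation_restore(ramp, cores)
        interior = np.zeros((h, w), dtype=bool)
        interior[1:31, 1:31] = True  # strictly inside the hull
        assert np.abs(out[interior] - ramp[interior]).max() < 1e-6

    def test_vertex_pixel_keeps_core_value(self):
        rng = np.random.default_rng(0)
        img = rng.random((30, 30))
        cores = self.grid_cores(30, 30)
        out = baselines.interpolation_restore(img, cores)
        for r, c in cores.centers[:5]:
            assert out[int(r), int(c)] == pytest.approx(img[int(r), int(c)],
                                                        abs=1e-9)

    def test_output_bounded_by_core_value_range(self):
        rng = np.random.default_rng(2)
        img = rng.random((30, 30))
        cores = baselines.sample_cores(img, self.grid_cores(30, 30))
        out = baselines.interpolation_restore(img, cores)
        hull = np.zeros((30, 30), dtype=bool)
        hull[:25, :25] = True
        assert out[hull].min() >= cores.values.min() - 1e-9
        assert out[hull].max() <= cores.values.max() + 1e-9

    def test_collinear_cores_rejected(self):
        cores = CoreMap(np.array([[0.0, 0.0], [5.0, 5.0], [10.0, 10.0]]))
        with pytest.raises(ValueError):
            baselines.interpolation_restore(np.ones((12, 12)), cores)

    def test_too_few_cores_rejected(self):
        with pytest.raises(ValueError):
            baselines.interpolation_restore(np.ones((12, 12)),
                                            CoreMap(np.array([[1.0, 1.0]])))
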