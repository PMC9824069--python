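"""Metric identities and closed forms: PSNR, SSIM, s, r, q."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from debundle import metrics
from debundle.metrics import RegionSpec


class TestPsnr:
    def test_identical_images_infinite(self):
        x = np.random.default_rng(0).random((16, 16))
        assert metrics.psnr(x, x) == np.inf

    def test_full_scale_difference_zero_db(self):
        a = np.zeros((8, 8))
        b = np.full((8, 8), 255.0)
        assert metrics.psnr(a, b, input_max=255.0) == pytest.approx(0.0)

    def test_unit_difference_closed_form(self):
        a = np.zeros((8, 8))
        b = np.ones((8, 8))
        expected = 20 * np.log10(255.0)  # ~48.13 dB
        assert metrics.psnr(a, b, input_max=255.0) == pytest.approx(expected)

    def test_unit_and_8bit_scales_agree(self):
        rng = np.random.default_rng(1)
        x, y = rng.random((12, 12)), rng.random((12, 12))
        assert metrics.psnr(x, y) == pytest.approx(
            metrics.psnr(x * 255, y * 255, input_max=255.0))

    def test_decreases_with_noise_level(self):
        rng = np.random.default_rng(2)
        x = rng.random((32, 32))
        noise = rng.standard_normal((32, 32))
        values = [metrics.psnr(x, x + s * noise)
                  for s in (0.01, 0.02, 0.05, 0.1, 0.2)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestSsim:
    def test_self_similarity_is_one(self):
        x = np.random.default_rng(0).random((32, 32))
        for window in ("gaussian", "global"):
            assert metrics.ssim(x, x, window=window) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.random((32, 32)), rng.random((32, 32))
        assert metrics.ssim(x, y) == pytest.approx(metrics.ssim(y, x))

    @pytest.mark.parametrize("a,b", [(0.2, 0.8), (0.5, 0.5), (0.1, 1.0)])
    def test_constant_images_closed_form(self, a, b):
        # variance terms vanish; second factor is c2/c2 = 1
        L = 255.0
        c1 = (0.01 * L) ** 2
        av, bv = a * L, b * L
        expected = (2 * av * bv + c1) / (av**2 + bv**2 + c1)
        x, y = np.full((16, 16), a), np.full((16, 16), b)
        assert metrics.ssim(x, y, window="global") == pytest.approx(expected)
        assert metrics.ssim(x, y) == pytest.approx(expected)

    def test_bounded_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            v = metrics.ssim(rng.random((24, 24)), rng.random((24, 24)))
            assert -1.0 <= v <= 1.0


FLAT = RegionSpec("flat", rows=(2, 13), cols=(2, 13))
LINES = RegionSpec("lines", rows=(2, 13), cols=(2, 13))


class TestSmoothness:
    def test_unchanged_image_scores_zero(self):
        raw = np.random.default_rng(0).random((16, 16))
        assert metrics.smoothness(raw, raw, FLAT) == pytest.approx(0.0)

    def test_perfectly_flattened_scores_one(self):
        raw = np.random.default_rng(1).random((16, 16))
        assert metrics.smoothness(raw, np.full((16, 16), 0.3), FLAT) == 1.0

    def test_half_spread_scores_half(self):
        raw = np.random.default_rng(2).random((16, 16))
        sub = FLAT.extract(raw)
        shrunk = raw.copy()
        shrunk[2:14, 2:14] = sub.mean() + 0.5 * (sub - sub.mean())
        assert metrics.smoothness(raw, shrunk, FLAT) == pytest.approx(0.5)

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(3)
        raw, restored = rng.random((16, 16)), rng.random((16, 16))
        s0 = metrics.smoothness(raw, restored, FLAT)
        s1 = metrics.smoothness(raw, restored + 0.2, FLAT)
        assert s0 == pytest.approx(s1)

    def test_zero_raw_variance_rejected(self):
        with pytest.raises(ValueError):
            metrics.smoothness(np.ones((16, 16)), np.ones((16, 16)), FLAT)

    def test_wrong_region_kind_rejected(self):
        with pytest.raises(ValueError):
            metrics.smoothness(np.ones((16, 16)), np.ones((16, 16)), LINES)


class TestLineSeparation:
    @staticmethod
    def bars(lo, hi, shape=(16, 16)):
        img = np.full(shape, lo)
        img[::2] = hi
        return img

    def test_perfect_bars_score_one(self):
        assert metrics.line_separation(self.bars(0.0, 1.0), LINES) == 1.0

    def test_constant_region_scores_zero(self):
        assert metrics.line_separation(np.full((16, 16), 0.4), LINES) == 0.0

    def test_partial_contrast_closed_form(self):
        assert metrics.line_separation(self.bars(0.2, 1.0), LINES) == (
            pytest.approx(0.8))

    def test_not_invariant_to_additive_offset(self):
        # r is max-normalized, so adding a pedestal changes it
        r0 = metrics.line_separation(self.bars(0.2, 1.0), LINES)
        r1 = metrics.line_separation(self.bars(0.2, 1.0) + 0.5, LINES)
        assert r1 != pytest.approx(r0)

    def test_vertical_bars_via_line_axis(self):
        img = self.bars(0.1, 0.9).T
        region = RegionSpec("lines", rows=(2, 13), cols=(2, 13), line_axis=1)
        assert metrics.line_separation(img, region) == pytest.approx(
            metrics.line_separation(self.bars(0.1, 0.9), LINES))


class TestWeightedQuality:
    def test_endpoints_return_components(self):
        assert metrics.weighted_quality(0.3, 0.7, 1.0) == 0.3
        assert metrics.weighted_quality(0.3, 0.7, 0.0) == 0.7

    @given(s=st.floats(0, 1), r=st.floats(0, 1),
           g1=st.floats(0, 1), g2=st.floats(0, 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_affine_in_gamma_and_monotone_in_s(self, s, r, g1, g2):
        mid = metrics.weighted_quality(s, r, (g1 + g2) / 2)
        ends = 0.5 * (metrics.weighted_quality(s, r, g1)
                      + metrics.weighted_quality(s, r, g2))
        assert mid == pytest.approx(ends, abs=1e-12)
        if g1 > 0:
            assert metrics.weighted_quality(min(s + 0.1, 1.0), r, g1) >= (
                metrics.weighted_quality(s, r, g1))

    def test_gamma_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            metrics.weighted_quality(0.5, 0.5, 1.2)


class TestEvaluate:
    def test_report_q_consistent_with_components(self):
        rng = np.random.default_rng(0)
        raw = rng.random((32, 32))
        restored = 0.5 + 0.25 * (raw - 0.5)
        truth = np.full((32, 32), 0.5)
        regions = {"flat": RegionSpec("flat", (2, 29), (2, 29)),
                   "lines": RegionSpec("lines", (2, 29), (2, 29))}
        rep = metrics.evaluate(restored, truth=truth, raw=raw,
                               regions=regions, gammas=(0.0, 0.5, 1.0))
        assert rep.q[1.0] == pytest.approx(rep.s, abs=1e-12)
        assert rep.q[0.0] == pytest.approx(rep.r, abs=1e-12)
        assert rep.psnr is not None and rep.ssim is not None
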