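"""Linescans, Manders coefficients and the nMDP map against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endopolar import (extract_linescan, generate_coloc_fixture,
                       manders_coefficients, nmdp_map, profile_correlation)


def manders_bruteforce(a, b, ta, tb):
    """Double-loop reference implementation of thresholded M1/M2."""
    num1 = den1 = num2 = den2 = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            if a[i, j] > ta:
                den1 += a[i, j]
                if b[i, j] > tb:
                    num1 += a[i, j]
            if b[i, j] > tb:
                den2 += b[i, j]
                if a[i, j] > ta:
                    num2 += b[i, j]
    return num1 / den1, num2 / den2


def nmdp_bruteforce(a, b):
    out = np.empty_like(a, dtype=float)
    am, bm = a.mean(), b.mean()
    den = (a.max() - am) * (b.max() - bm)
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            v = (a[i, j] - am) * (b[i, j] - bm) / den
            # the map clamps to the nominal [-1, 1] display range
            out[i, j] = min(1.0, max(-1.0, v))
    return out


class TestLinescan:
    def test_constant_image_flat_at_100(self):
        img = np.full((32, 32), 37.0)
        prof = extract_linescan(img, img, np.array([[16, 4], [16, 28]]))
        np.testing.assert_allclose(prof.normalized, 100.0)

    def test_ramp_profile_matches_pixel_loop(self):
        # horizontal line across a ramp in x: width-averaged values equal
        # the ramp read off by a direct loop (perpendicular offsets are
        # along y where the ramp is constant)
        ramp = np.tile(np.arange(64, dtype=float), (64, 1))
        poly = np.array([[32.0, 10.0], [32.0, 50.0]])
        prof = extract_linescan(ramp, ramp, poly, width=6)
        expected = []
        for k in range(len(prof.positions)):
            x = 10.0 + k
            vals = [ramp[int(32 + o), int(x)] for o in (-2.5, -1.5, -.5, .5, 1.5, 2.5)]
            expected.append(np.mean(vals))
        np.testing.assert_allclose(prof.raw[0], expected, atol=1e-9)

    def test_normalized_max_exactly_100(self, rng):
        a = rng.random((48, 48)) * 200.0
        b = rng.random((48, 48)) * 55.0
        prof = extract_linescan(a, b, np.array([[10, 10], [40, 35]]))
        assert prof.normalized[0].max() == 100.0
        assert prof.normalized[1].max() == 100.0

    def test_sample_count_matches_arc_length(self):
        poly = np.array([[5.0, 5.0], [5.0, 25.0], [20.0, 25.0]])  # length 35
        img = np.ones((64, 64))
        prof = extract_linescan(img, img, poly)
        assert abs(len(prof.positions) - 36) <= 1

    def test_out_of_bounds_polyline_rejected(self):
        img = np.ones((32, 32))
        with pytest.raises(ValueError):
            extract_linescan(img, img, np.array([[1, 1], [1, 31]]))


class TestProfileCorrelation:
    def _profile(self, a, b):
        from endopolar.colocalization import LinescanProfile
        raw = np.stack([a, b])
        norm = raw * (100.0 / raw.max(axis=1, keepdims=True))
        return LinescanProfile(vertices=np.zeros((2, 2)),
                               positions=np.arange(len(a), dtype=float),
                               raw=raw, normalized=norm, width=6)

    def test_identical_channels(self):
        a = np.array([1.0, 5.0, 3.0, 8.0, 2.0])
        r, slope, intercept = profile_correlation(self._profile(a, a))
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_anticorrelated_channels(self):
        a = np.linspace(1, 100, 50)
        r, _, _ = profile_correlation(self._profile(a, 101.0 - a))
        assert r == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self, rng):
        a = rng.random(10_000) * 100
        b = rng.random(10_000) * 100
        r, _, _ = profile_correlation(self._profile(a, b))
        assert abs(r) < 0.05

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            profile_correlation(self._profile(np.ones(5), np.arange(5.0) + 1))


class TestManders:
    def test_worked_four_pixel_example(self):
        a = np.array([[10.0, 10.0], [0.0, 0.0]])
        b = np.array([[5.0, 0.0], [5.0, 0.0]])
        res = manders_coefficients(a, b, threshold_a=1.0, threshold_b=1.0)
        assert res.m1 == pytest.approx(0.5)
        assert res.m2 == pytest.approx(0.5)

    def test_full_overlap(self, rng):
        a = rng.random((16, 16)) * 100 + 10
        res = manders_coefficients(a, a + 5, threshold_a=1.0, threshold_b=1.0)
        assert res.m1 == 1.0 and res.m2 == 1.0

    def test_disjoint_supports(self):
        a = np.zeros((4, 4)); a[:2] = 50.0
        b = np.zeros((4, 4)); b[2:] = 50.0
        res = manders_coefficients(a, b, threshold_a=1.0, threshold_b=1.0)
        assert res.m1 == 0.0 and res.m2 == 0.0

    def test_matches_bruteforce_random_pairs(self, rng):
        for _ in range(20):
            a = rng.random((16, 16)) * 100
            b = rng.random((16, 16)) * 100
            m1, m2 = manders_bruteforce(a, b, 30.0, 60.0)
            res = manders_coefficients(a, b, threshold_a=30.0, threshold_b=60.0)
            assert res.m1 == pytest.approx(m1, rel=1e-12)
            assert res.m2 == pytest.approx(m2, rel=1e-12)

    @given(gain=st.floats(0.1, 50))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_with_scaled_thresholds(self, gain):
        rng = np.random.default_rng(0)
        a = rng.random((12, 12)) * 100
        b = rng.random((12, 12)) * 100
        base = manders_coefficients(a, b, threshold_a=40.0, threshold_b=40.0)
        scaled = manders_coefficients(a * gain, b, threshold_a=40.0 * gain,
                                      threshold_b=40.0)
        assert scaled.m1 == pytest.approx(base.m1, rel=1e-9)
        assert scaled.m2 == pytest.approx(base.m2, rel=1e-9)

    def test_undefined_when_denominator_empty(self):
        with pytest.raises(ValueError):
            manders_coefficients(np.zeros((4, 4)), np.ones((4, 4)),
                                 threshold_a=1.0, threshold_b=0.5)

    def test_mask_restricts_computation(self, rng):
        a = rng.random((16, 16)) * 100
        b = rng.random((16, 16)) * 100
        mask = np.zeros((16, 16), bool)
        mask[:8] = True
        res = manders_coefficients(a, b, threshold_a=30.0, threshold_b=30.0,
                                   mask=mask)
        m1, m2 = manders_bruteforce(a[:8], b[:8], 30.0, 30.0)
        assert res.m1 == pytest.approx(m1, rel=1e-12)

    def test_monotone_in_planted_overlap(self):
        m1s = []
        for i, rho in enumerate((0.0, 0.25, 0.5, 0.75, 1.0)):
            scene, _ = generate_coloc_fixture(rho=rho, seed=i)
            a, b = scene.plane(0), scene.plane(1)
            res = manders_coefficients(a, b, threshold_a=1.0, threshold_b=1.0)
            m1s.append(res.m1)
        assert all(x < y for x, y in zip(m1s, m1s[1:]))


class TestNMDP:
    def test_identity_case(self, rng):
        a = rng.random((8, 8)) * 100
        out = nmdp_map(a, a)
        assert out[np.unravel_index(a.argmax(), a.shape)] == pytest.approx(1.0)
        assert np.all(out[a > a.mean()] > 0)

    def test_anticorrelation_case(self, rng):
        a = rng.random((8, 8)) * 100
        out = nmdp_map(a, 200.0 - a)
        assert np.all(out[a > a.mean()] <= 0)

    def test_matches_double_loop(self, rng):
        a = rng.random((8, 8)) * 50
        b = rng.random((8, 8)) * 50
        np.testing.assert_allclose(nmdp_map(a, b), nmdp_bruteforce(a, b),
                                   rtol=1e-12)

    @given(gain=st.floats(0.1, 20), offset=st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, gain, offset):
        rng = np.random.default_rng(1)
        a = rng.random((8, 8)) * 100
        b = rng.random((8, 8)) * 100
        np.testing.assert_allclose(nmdp_map(a * gain + offset, b),
                                   nmdp_map(a, b), atol=1e-9)

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError):
            nmdp_map(np.ones((4, 4)), np.random.default_rng(0).random((4, 4)))
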