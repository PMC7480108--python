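"""Velocity-frame polar transform, rose histograms, front fraction, Rao test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from endopolar import (assign_endosomes, front_fraction, polar_transform,
                       rao_spacing_test, rao_u_statistic, sample_von_mises,
                       sector_histogram)
from endopolar.segmentation import SpotSet
from tests.test_synthetic import vm_interval_mass


def _rotation_oracle(spot, nucleus, velocity):
    """Independent computation of theta via explicit rotation matrices in
    math coordinates (x right, y up): rotate the frame so the velocity is
    the +x axis, then read the angle of the rotated spot vector."""
    sy, sx = spot[0] - nucleus[0], spot[1] - nucleus[1]
    s = np.array([sx, -sy])              # to math coords
    v = np.array([velocity[1], -velocity[0]])
    phi = math.atan2(v[1], v[0])
    R = np.array([[math.cos(-phi), -math.sin(-phi)],
                  [math.sin(-phi), math.cos(-phi)]])
    rs = R @ s
    return math.degrees(math.atan2(rs[1], rs[0]))


class TestPolarTransform:
    def test_spot_ahead_is_zero(self):
        # nucleus moving right (+x in image coords), spot to its right
        _, theta = polar_transform((10, 20), (10, 10), (0, 5))
        assert theta == 0.0

    def test_spot_behind_is_180(self):
        _, theta = polar_transform((10, 0), (10, 10), (0, 5))
        assert theta == 180.0

    def test_sign_convention_y_down(self):
        # velocity +x, spot offset (0, +1) in (dy, dx) image coords -> -90
        _, theta = polar_transform((11, 10), (10, 10), (0, 1))
        assert theta == pytest.approx(-90.0)

    def test_radius_in_um(self):
        r, _ = polar_transform((13, 14), (10, 10), (0, 1), pixel_size=0.5)
        assert r == pytest.approx(0.5 * 5.0)

    def test_matches_rotation_matrix_oracle(self, rng):
        for _ in range(100):
            nucleus = rng.uniform(0, 50, 2)
            spot = nucleus + rng.uniform(-20, 20, 2)
            velocity = rng.uniform(-5, 5, 2)
            if np.hypot(*velocity) < 0.5 or np.hypot(*(spot - nucleus)) < 1e-6:
                continue
            _, theta = polar_transform(spot, nucleus, velocity)
            assert theta == pytest.approx(
                _rotation_oracle(spot, nucleus, velocity), abs=1e-9)

    def test_subthreshold_velocity_rejected(self):
        with pytest.raises(ValueError):
            polar_transform((10, 20), (10, 10), (0.05, 0.05), pixel_size=1.0)

    def test_rotation_equivariance(self, rng):
        # rotating spot offset and velocity together leaves theta unchanged
        nucleus = np.array([50.0, 50.0])
        offset = np.array([-7.0, 11.0])
        velocity = np.array([2.0, 3.0])
        _, base = polar_transform(nucleus + offset, nucleus, velocity)
        for _ in range(8):
            a = rng.uniform(0, 2 * math.pi)
            R = np.array([[math.cos(a), -math.sin(a)],
                          [math.sin(a), math.cos(a)]])
            _, theta = polar_transform(nucleus + R @ offset, nucleus,
                                       R @ velocity)
            assert theta == pytest.approx(base, abs=1e-9)


class TestAssignEndosomes:
    def _spots(self, pts):
        return SpotSet(table=pd.DataFrame(
            [dict(frame=0, y=p[0], x=p[1], response=1.0, flux=1.0,
                  border=False) for p in pts]))

    def test_all_within_radius_assigned(self):
        out = assign_endosomes(self._spots([(10, 10), (12, 14)]),
                               np.array([[11.0, 11.0]]), [3], max_radius=10.0)
        assert (out["cell_id"] == 3).all()
        assert out.attrs["n_unassigned"] == 0

    def test_equidistant_tie_goes_to_lower_id(self):
        out = assign_endosomes(self._spots([(10, 15)]),
                               np.array([[10.0, 10.0], [10.0, 20.0]]),
                               [7, 2], max_radius=10.0)
        assert out["cell_id"].iloc[0] == 2

    def test_out_of_radius_dropped(self):
        out = assign_endosomes(self._spots([(0, 0), (50, 50)]),
                               np.array([[0.0, 0.0]]), [0], max_radius=5.0)
        assert len(out) == 1
        assert out.attrs["n_unassigned"] == 1

    def test_no_nuclei_warns(self):
        with pytest.warns(UserWarning):
            out = assign_endosomes(self._spots([(1, 1)]), np.empty((0, 2)),
                                   [], max_radius=5.0)
        assert len(out) == 0


class TestSectorHistogram:
    def test_all_zero_degrees(self):
        h = sector_histogram(np.zeros(50))
        assert h.percentages[list(h.centers_deg).index(0.0)] == 100.0

    def test_twelve_bin_centers(self):
        h = sector_histogram(np.array(
            [0, 30, 60, 90, 120, 150, 180, -150, -120, -90, -60, -30], float))
        np.testing.assert_allclose(h.percentages, 100 / 12)

    def test_uniform_sample_flat_within_binomial_noise(self):
        a = sample_von_mises(0, 0, 10_000, seed=12)
        h = sector_histogram(a)
        assert np.all(np.abs(h.percentages - 100 / 12) < 1.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sector_histogram(np.array([]))

    @given(st.lists(st.floats(-180, 180, exclude_min=True), min_size=1,
                    max_size=300))
    @settings(max_examples=100, deadline=None)
    def test_percentages_sum_to_100(self, angles):
        h = sector_histogram(np.array(angles))
        assert h.percentages.sum() == pytest.approx(100.0, abs=1e-9)
        assert h.counts.sum() == len(angles)

    def test_front_fraction_consistent_with_binning(self):
        # when angles occupy only bins wholly inside (or outside) the
        # 120 deg front sector, the raw front fraction equals the summed
        # bin percentages; bins straddling ±60 deg are left empty
        rng = np.random.default_rng(3)
        centers = np.array([0, 30, -30, 120, 180, -90])
        a = np.concatenate([c + rng.uniform(-10, 10, 40) for c in centers])
        h = sector_histogram(a)
        inside = np.isin(h.centers_deg, [-30, 0, 30])
        assert front_fraction(a) == pytest.approx(h.percentages[inside].sum())


class TestFrontFraction:
    def test_uniform(self):
        a = sample_von_mises(0, 0, 100_000, seed=8)
        assert front_fraction(a) == pytest.approx(100 / 3, abs=0.5)

    def test_delta_at_zero(self):
        assert front_fraction(np.zeros(10)) == 100.0

    def test_von_mises_matches_quadrature(self):
        a = sample_von_mises(0, 1.5, 100_000, seed=9)
        expected = 100 * vm_interval_mass(1.5, -60, 60)
        assert front_fraction(a) == pytest.approx(expected, abs=0.5)


class TestRaoSpacing:
    def test_perfectly_even_angles(self):
        res = rao_spacing_test(np.array([0.0, 90.0, 180.0, 270.0]),
                               n_mc=2000, seed=0)
        assert res.U == 0.0
        assert res.p_value > 0.99

    def test_identical_angles_hand_formula(self):
        # n identical angles: spacings {0,...,0,360}, U = 360 (n-1)/n
        U, spacings = rao_u_statistic(np.full(10, 42.0))
        assert U == pytest.approx(360 * 9 / 10)
        assert spacings.sum() == pytest.approx(360.0)
        res = rao_spacing_test(np.full(10, 42.0), n_mc=10_000, seed=1)
        assert res.p_value < 0.001

    def test_spacings_sum_to_360(self, rng):
        U, spacings = rao_u_statistic(rng.uniform(-180, 180, 23))
        assert spacings.sum() == pytest.approx(360.0)
        assert U >= 0

    def test_too_few_angles(self):
        with pytest.raises(ValueError):
            rao_spacing_test(np.array([0.0, 10.0, 20.0]))

    def test_statistic_rotation_invariant(self, rng):
        a = rng.uniform(-180, 180, 40)
        U0, _ = rao_u_statistic(a)
        from endopolar.synthetic import wrap_degrees
        for shift in (13.0, 120.0, -77.0):
            U1, _ = rao_u_statistic(wrap_degrees(a + shift))
            assert U1 == pytest.approx(U0, abs=1e-9)

    def test_power_monotone_in_concentration(self):
        # rejection rate non-decreasing over kappa at fixed n
        rates = []
        for i, kappa in enumerate((0.0, 0.5, 1.0, 2.0)):
            rej = 0
            for s in range(500):
                a = sample_von_mises(0, kappa, 30, seed=1000 * i + s)
                if rao_spacing_test(a, n_mc=2000, seed=2).p_value < 0.05:
                    rej += 1
            rates.append(rej / 500)
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 0.9
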