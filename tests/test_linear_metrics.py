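"""Co-contribution, center of activity, FWHM, exceedance and overlap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synergait import (Bump, co_contribution_index, center_of_activity,
                       exceedance_frequency, full_width_half_max,
                       half_max_indicator, is_bimodal, make_primitive,
                       overlap_frequency, primitive_metrics)
from synergait.linear_metrics import count_half_max_runs

MUSCLES = ("TA", "GaM", "GaL", "SOL", "PL", "VM", "VL", "RF", "BF", "STSM", "GM")


def _module(**weights):
    w = np.zeros(len(MUSCLES))
    for name, val in weights.items():
        w[MUSCLES.index(name)] = val
    return w


class TestCoContributionIndex:
    def test_anterior_only_gives_one(self):
        w = _module(TA=0.8)
        assert co_contribution_index(w, MUSCLES, "ankle") == pytest.approx(1.0)

    def test_posterior_only_gives_zero(self):
        w = _module(GaM=1.0, SOL=0.5)
        assert co_contribution_index(w, MUSCLES, "ankle") == pytest.approx(0.0)

    def test_equal_group_means_give_half(self):
        w = _module(RF=0.4, GM=0.4)
        assert co_contribution_index(w, MUSCLES, "hip") == pytest.approx(0.5)

    def test_knee_group_means(self):
        # mean(ant) = mean(RF, VL, VM) = 0.6; mean(post) = mean(STSM, BF) = 0.3
        w = _module(RF=0.6, VL=0.6, VM=0.6, STSM=0.3, BF=0.3)
        assert co_contribution_index(w, MUSCLES, "knee") == pytest.approx(2 / 3)

    def test_zero_groups_rejected(self):
        with pytest.raises(ValueError):
            co_contribution_index(_module(VM=1.0), MUSCLES, "ankle")

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None)
    def test_scale_invariance(self, c):
        w = _module(TA=0.3, GaM=0.5, SOL=0.2)
        assert co_contribution_index(c * w, MUSCLES, "ankle") == pytest.approx(
            co_contribution_index(w, MUSCLES, "ankle"))


class TestCenterOfActivity:
    def test_impulse_at_touchdown_is_zero_degrees(self):
        h = np.zeros(200)
        h[0] = 1.0
        assert center_of_activity(h) == pytest.approx(0.0)

    def test_impulse_at_half_cycle_is_180_degrees(self):
        h = np.zeros(200)
        h[100] = 1.0  # point 101, start of flight
        assert center_of_activity(h) == pytest.approx(180.0)

    def test_symmetric_bump_center(self):
        h = make_primitive([Bump(center=51, width=30)])
        assert center_of_activity(h) == pytest.approx(90.0, abs=1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            center_of_activity(np.zeros(200))

    @given(st.integers(min_value=0, max_value=199))
    @settings(deadline=None)
    def test_circular_shift_equivariance(self, shift):
        h = make_primitive([Bump(center=40, width=25)])
        base = center_of_activity(h)
        rotated = center_of_activity(np.roll(h, shift))
        expected = (base + 360.0 * shift / 200.0) % 360.0
        assert rotated == pytest.approx(expected, abs=1e-6) or \
            abs(rotated - expected) == pytest.approx(360.0, abs=1e-6)


class TestFullWidthHalfMax:
    def test_rectangular_pulse(self):
        h = np.zeros(200)
        h[30:70] = 1.0
        assert full_width_half_max(h) == 40

    def test_symmetric_triangle(self):
        h = np.zeros(200)
        h[50:150] = 1.0 - np.abs(np.arange(100) - 49.5) / 50.0
        assert abs(full_width_half_max(h) - 50) <= 1

    def test_full_cycle_sinusoid(self):
        t = np.arange(200)
        h = 1.0 + np.sin(2 * np.pi * t / 200)
        assert abs(full_width_half_max(h) - 100) <= 1

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            full_width_half_max(np.ones(200))

    @given(st.floats(min_value=0.1, max_value=10.0),
           st.floats(min_value=-5.0, max_value=5.0))
    @settings(deadline=None)
    def test_affine_invariance(self, a, b):
        h = make_primitive([Bump(center=80, width=45)])
        assert full_width_half_max(a * h + b) == full_width_half_max(h)


class TestExceedanceFrequency:
    def test_identical_cycles_give_binary_frequencies(self):
        cyc = make_primitive([Bump(center=60, width=40)])
        freq = exceedance_frequency(np.tile(cyc, (10, 1)))
        assert set(np.unique(freq)) <= {0.0, 1.0}

    def test_counting_fraction(self):
        a = np.zeros(200); a[40:80] = 1.0; a[0] = 0.01
        b = np.zeros(200); b[100:140] = 1.0; b[0] = 0.01
        freq = exceedance_frequency(np.vstack([np.tile(a, (30, 1)),
                                               np.tile(b, (30, 1))]))
        assert freq[50] == pytest.approx(0.5)
        assert freq[120] == pytest.approx(0.5)
        assert freq[0] == 0.0

    def test_jittered_bumps_form_plateau_with_shoulders(self, rng):
        cycles = np.vstack([
            make_primitive([Bump(center=100 + int(d), width=40)])
            for d in rng.integers(-5, 6, size=60)
        ])
        freq = exceedance_frequency(cycles)
        assert freq[99] == 1.0                      # always inside the half-max run
        assert 0.0 < freq[78] < 1.0 or 0.0 < freq[121] < 1.0  # shoulders
        assert freq[0] == 0.0

    def test_brute_force_oracle(self, rng):
        cycles = rng.uniform(0, 1, (7, 200))
        freq = exceedance_frequency(cycles)
        expected = np.zeros(200)
        for c in range(7):
            lo, hi = cycles[c].min(), cycles[c].max()
            expected += (cycles[c] - lo) > (hi - lo) / 2
        np.testing.assert_allclose(freq, expected / 7)


class TestOverlapFrequency:
    def test_shared_support(self):
        ind = np.zeros((2, 5, 200), dtype=bool)
        ind[:, :, 60:80] = True
        freq = overlap_frequency(ind)
        np.testing.assert_allclose(freq[60:80], 1.0)
        assert freq.sum() == pytest.approx(20.0)

    def test_disjoint_supports_never_overlap(self):
        ind = np.zeros((2, 5, 200), dtype=bool)
        ind[0, :, 20:40] = True
        ind[1, :, 120:140] = True
        assert overlap_frequency(ind).max() == 0.0

    def test_three_synergies_against_indicator_count(self, rng):
        ind = rng.uniform(size=(3, 12, 200)) < 0.4
        freq = overlap_frequency(ind)
        expected = np.array([
            np.mean([ind[:, c, p].sum() >= 2 for c in range(12)])
            for p in range(200)
        ])
        np.testing.assert_allclose(freq, expected)

    def test_single_synergy_rejected(self):
        with pytest.raises(ValueError):
            overlap_frequency(np.ones((1, 5, 200), dtype=bool))

    def test_bounded_by_second_largest_exceedance(self, rng):
        cycles = np.stack([
            np.vstack([make_primitive([Bump(center=c0 + int(d), width=60)])
                       for d in rng.integers(-8, 9, size=20)])
            for c0 in (60, 90, 150)
        ])
        ind = np.stack([[half_max_indicator(cycles[j, c]) for c in range(20)]
                        for j in range(3)])
        over = overlap_frequency(ind)
        exceed = ind.mean(axis=1)
        second = np.sort(exceed, axis=0)[-2]
        assert (over <= second + 1e-12).all()


class TestBimodality:
    def test_single_bump_one_run(self):
        assert count_half_max_runs(make_primitive([Bump(100, 40)])) == 1
        assert not is_bimodal(make_primitive([Bump(100, 40)]))

    def test_two_bumps_two_runs(self):
        p = make_primitive([Bump(60, 25), Bump(160, 25, 0.9)])
        assert count_half_max_runs(p) == 2
        assert is_bimodal(p)

    def test_run_wrapping_cycle_boundary_counted_once(self):
        p = make_primitive([Bump(1, 30)])
        assert count_half_max_runs(p) == 1


class TestPrimitiveMetrics:
    def test_bundle_consistent_with_parts(self):
        tmpl = [make_primitive([Bump(50, 40)]), make_primitive([Bump(150, 40)])]
        H = np.vstack([np.tile(t, 5) for t in tmpl])
        met = primitive_metrics(H)
        assert met.coa_deg.shape == (2,)
        assert met.fwhm_points[0] == full_width_half_max(tmpl[0])
        assert met.exceedance_freq.shape == (2, 200)
        assert not met.bimodal.any()
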