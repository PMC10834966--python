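"""Gait events, filtering, normalization and the 200-point cycle grid."""

import numpy as np
import pytest

from synergait import (center_of_activity, detect_gait_events, filter_emg,
                       full_width_half_max, normalize_amplitude,
                       select_last_cycles, spatiotemporal_params,
                       time_normalize)
from synergait.preprocessing import EmgCycleTensor, GaitEvents
from synergait.synthetic import default_ground_truth, generate_recording


def _square_force(stance=25, flight=75, n_cycles=5, high=800.0):
    f = np.zeros(n_cycles * (stance + flight) + flight)
    for c in range(n_cycles):
        a = flight // 2 + c * (stance + flight)
        f[a:a + stance] = high
    return f


class TestDetectGaitEvents:
    def test_step_crossing_reported_at_first_sample_at_threshold(self):
        force = np.zeros(100)
        force[37:80] = 100.0
        ev = detect_gait_events(force, 50.0)
        assert ev.touchdowns[0] == 37
        assert ev.toeoffs[0] == 80

    def test_constant_zero_force_raises(self):
        with pytest.raises(ValueError):
            detect_gait_events(np.zeros(100), 50.0)

    def test_synthetic_force_yields_programmed_cycle_count(self, preset_recording):
        ev = detect_gait_events(preset_recording.force, 50.0,
                                rate=preset_recording.force_rate)
        # brute-force crossing scan as oracle
        above = preset_recording.force >= 50.0
        ups = np.flatnonzero(~above[:-1] & above[1:]) + 1
        np.testing.assert_array_equal(ev.touchdowns, ups)
        assert ev.n_cycles == preset_recording.truth.n_cycles

    def test_scale_invariance_on_plateaus(self):
        f = _square_force()
        a = detect_gait_events(f, 50.0)
        b = detect_gait_events(3.0 * f, 50.0)
        np.testing.assert_array_equal(a.touchdowns, b.touchdowns)
        np.testing.assert_array_equal(a.toeoffs, b.toeoffs)

    def test_debounce_merges_threshold_chatter(self):
        f = _square_force(stance=30, flight=70, n_cycles=3)
        f[52:54] = 0.0  # 20 ms dropout inside a stance
        ev = detect_gait_events(f, 50.0, rate=100.0, debounce_s=0.05)
        assert len(ev.touchdowns) == 3
        raw = detect_gait_events(f, 50.0, rate=100.0, debounce_s=None)
        assert len(raw.touchdowns) == 4

    def test_incomplete_leading_stance_dropped(self):
        f = _square_force()
        f = f[40:]  # start mid-stance? start inside first flight half; shift more
        f2 = np.concatenate([[800.0] * 10, f])  # starts mid-stance
        ev = detect_gait_events(f2, 50.0)
        assert f2[ev.touchdowns[0] - 1] < 50.0


class TestSpatiotemporal:
    def test_arithmetic(self):
        ev = GaitEvents(touchdowns=[0, 100, 200], toeoffs=[25, 125, 225])
        st = spatiotemporal_params(ev, rate=100.0)
        assert st.stance_time[0] == pytest.approx(0.25)
        assert st.flight_time[0] == pytest.approx(0.75)
        assert st.stride_frequency[0] == pytest.approx(1.0)

    def test_equal_phases(self):
        ev = GaitEvents(touchdowns=[0, 100, 200], toeoffs=[50, 150, 250])
        st = spatiotemporal_params(ev, rate=100.0)
        np.testing.assert_allclose(st.stance_time, st.flight_time)

    def test_too_few_cycles_rejected(self):
        ev = GaitEvents(touchdowns=[0, 100], toeoffs=[25, 125])
        with pytest.raises(ValueError):
            spatiotemporal_params(ev, rate=100.0)

    def test_programmed_durations_recovered(self, preset_recording):
        ev = detect_gait_events(preset_recording.force, 50.0)
        st = spatiotemporal_params(ev, preset_recording.force_rate)
        assert np.abs(st.stance_time - 0.20).max() <= 0.01
        assert np.abs(st.flight_time - 0.15).max() <= 0.01


class TestFilterEmg:
    def test_zero_input_zero_output(self):
        out = filter_emg(np.zeros((2, 4000)), 2000.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_low_frequency_content_removed(self):
        t = np.arange(8000) / 2000.0
        x = np.sin(2 * np.pi * 5.0 * t)
        out = filter_emg(x, 2000.0)
        assert np.sqrt((out**2).mean()) < 0.05 * np.sqrt((x**2).mean())

    def test_carrier_demodulated_to_rectified_mean(self):
        # a 150 Hz carrier passes the band; rectification leaves a DC level
        # 2A/pi that the 20 Hz low-pass preserves
        t = np.arange(20000) / 2000.0
        A = 2.0
        x = A * np.sin(2 * np.pi * 150.0 * t)
        out = filter_emg(x, 2000.0)
        core = out[2000:-2000]  # away from filter edges
        assert core.mean() == pytest.approx(2 * A / np.pi, rel=0.1)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            filter_emg(np.zeros(1000), 1000.0)

    def test_envelope_nonnegative(self, rng):
        out = filter_emg(rng.standard_normal((3, 6000)), 2000.0)
        assert (out >= 0).all()


class TestNormalizeAmplitude:
    def test_affine_mapping_to_unit_interval(self):
        out = normalize_amplitude(np.array([[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(out, [[0.0, 0.5, 1.0]])

    def test_idempotent_on_unit_interval(self, rng):
        x = rng.uniform(0, 1, (2, 50))
        x[:, 0] = 0.0
        x[:, 1] = 1.0
        np.testing.assert_allclose(normalize_amplitude(x), x, atol=1e-12)

    def test_constant_channel_error_names_muscle(self):
        with pytest.raises(ValueError, match="GaM"):
            normalize_amplitude(np.vstack([np.arange(5.0), np.ones(5)]),
                                muscle_names=("TA", "GaM"))


class TestTimeNormalize:
    def test_constant_envelope_gives_constant_cycles(self):
        ev = GaitEvents(touchdowns=[0, 100, 200], toeoffs=[40, 140, 240])
        env = np.full((2, 4100), 3.0)
        tensor = time_normalize(env, ev, emg_rate=2000.0, force_rate=100.0)
        assert tensor.values.shape == (2, 200, 2)
        np.testing.assert_allclose(tensor.values, 3.0)

    def test_cycle_grid_is_200_points_100_stance(self, preset_recording):
        rec = preset_recording
        ev = detect_gait_events(rec.force, 50.0)
        tensor = time_normalize(rec.emg, ev, rec.emg_rate, rec.force_rate,
                                rec.muscle_names)
        assert tensor.values.shape[1] == 200
        assert tensor.n_cycles == rec.truth.n_cycles
        assert tensor.matrix.shape == (11, 200 * rec.truth.n_cycles)

    def test_stance_ramp_resampled_linearly(self):
        ev = GaitEvents(touchdowns=[0, 200], toeoffs=[100, 300])
        env = np.zeros((1, 2500))
        # ramp 0 -> 1 over the stance [0, 1 s) = EMG samples [0, 1000)
        env[0, :1000] = np.arange(1000) / 1000.0
        tensor = time_normalize(env, ev, emg_rate=1000.0, force_rate=100.0)
        expected = np.arange(100) / 100.0
        np.testing.assert_allclose(tensor.values[0, :100, 0], expected, atol=1e-6)

    def test_short_phase_rejected(self):
        ev = GaitEvents(touchdowns=[0, 4], toeoffs=[3, 7])
        with pytest.raises(ValueError):
            time_normalize(np.ones((1, 100)), ev, emg_rate=1.0, force_rate=1.0)


class TestSelectLastCycles:
    def _tensor(self, C):
        vals = np.arange(C)[None, None, :] * np.ones((2, 200, 1))
        return EmgCycleTensor(vals, ("a", "b"))

    def test_identity_when_exact(self):
        t = self._tensor(60)
        out = select_last_cycles(t, 60)
        np.testing.assert_array_equal(out.values, t.values)

    def test_keeps_trailing_cycles_in_order(self):
        out = select_last_cycles(self._tensor(80), 60)
        np.testing.assert_allclose(out.values[0, 0], np.arange(20, 80))

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            select_last_cycles(self._tensor(10), 60)


class TestEndToEndPreprocessing:
    def test_full_chain_normalized_and_recovers_bump_timing(self):
        truth = default_ground_truth(seed=3, noise_sigma=0.0)
        truth.modulation_amp = 0.0
        rec = generate_recording(truth)
        ev = detect_gait_events(rec.force, 50.0, rate=rec.force_rate)
        tensor = time_normalize(rec.emg, ev, rec.emg_rate, rec.force_rate,
                                rec.muscle_names)
        tensor = select_last_cycles(tensor, 60)
        tensor.values = normalize_amplitude(tensor.values, rec.muscle_names)
        flat = tensor.values.reshape(11, -1)
        assert flat.min() >= 0 and flat.max() <= 1
        np.testing.assert_allclose(flat.max(axis=1), 1.0)
        np.testing.assert_allclose(flat.min(axis=1), 0.0)
        # TA loads on the early-flight synergy only: its mean cycle should
        # recover that synergy's generating bump (center 115, width 50)
        ta = tensor.values[0].mean(axis=1)
        coa_expected = 360.0 * (115 - 1) / 200
        assert center_of_activity(ta) == pytest.approx(coa_expected, abs=3.6)
        assert abs(full_width_half_max(ta) - 50) <= 2
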