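"""EMA detection, post-processing rules, binarization and wave metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trace, rectangular_pulse_trace
from swbold.detect import (
    DetectionConfig,
    binarize_to_tr,
    calibrate_threshold,
    compute_threshold,
    detect_events,
    ema_filter,
    event_frequency,
    match_events,
    postprocess_events,
    quantify_wave_params,
    refine_terminations,
)
from swbold.preprocess import standard_preprocess
from swbold.simulate import preset, simulate_calcium_trace
from swbold.types import EventArray


def brute_force_ema(x, alpha):
    y = np.empty_like(x)
    y[0] = x[0]
    for i in range(1, x.size):
        y[i] = alpha * x[i] + (1 - alpha) * y[i - 1]
    return y


class TestEmaFilter:
    def test_constant_is_fixed_point(self):
        out = ema_filter(make_trace(np.full(100, 2.5)), 25.0)
        assert np.allclose(out.values, 2.5)

    def test_matches_recursion_oracle_on_impulse_and_step(self):
        alpha = 2.0 / (26)  # 25 ms window at 1 kHz
        impulse = np.zeros(200)
        impulse[0] = 1.0
        step = np.zeros(200)
        step[50:] = 1.0
        for x in (impulse, step):
            out = ema_filter(make_trace(x), 25.0)
            assert np.allclose(out.values, brute_force_ema(x, alpha), atol=1e-12)

    def test_delayed_step_closed_form(self):
        x = np.zeros(300)
        x[100:] = 1.0
        out = ema_filter(make_trace(x), 25.0)
        alpha = 2.0 / 26
        k = np.arange(200)
        assert np.allclose(out.values[100:], 1 - (1 - alpha) ** (k + 1), atol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_output_range_bounded_by_input_range(self, seed):
        x = np.random.default_rng(seed).normal(size=300)
        out = ema_filter(make_trace(x), 25.0)
        assert out.values.min() >= x.min() - 1e-12
        assert out.values.max() <= x.max() + 1e-12


class TestComputeThreshold:
    @staticmethod
    def _trace_with_reference(ref):
        # sorted sample #9500 of 10001 == ref -> 95th percentile == ref
        v = np.concatenate([np.linspace(0, ref, 9501), np.full(500, ref)])
        return make_trace(np.random.default_rng(0).permutation(v))

    def test_default_fractions_of_reference(self):
        on, term = compute_threshold(self._trace_with_reference(1.0))
        assert on == pytest.approx(0.70, abs=1e-9)
        assert term == pytest.approx(0.35, abs=1e-9)

    def test_threshold_scales_with_reference(self):
        on, term = compute_threshold(self._trace_with_reference(2.6))
        assert on == pytest.approx(1.82, abs=1e-9)
        assert term == pytest.approx(0.91, abs=1e-9)

    def test_single_outlier_does_not_set_reference(self):
        v = np.random.default_rng(1).uniform(0, 1.0, 1_000_000)
        v[1234] = 100.0
        on, _ = compute_threshold(make_trace(v))
        assert on < 0.75  # reference ~1, not 100

    def test_constant_trace_has_no_dynamic_range(self):
        with pytest.raises(ValueError, match="dynamic range"):
            compute_threshold(make_trace(np.zeros(100)))


class TestDetectEvents:
    def test_zero_trace_raises_no_dynamic_range(self):
        with pytest.raises(ValueError):
            detect_events(make_trace(np.zeros(1000)))

    def test_three_rectangular_pulses_detected_at_onsets(self):
        tr = rectangular_pulse_trace()
        ev = detect_events(tr)
        assert ev.n_events == 3
        assert np.allclose(ev.onsets_s, [1.0, 4.0, 7.0], atol=0.03)

    def test_sub_100ms_gap_reads_as_one_wave(self):
        tr = rectangular_pulse_trace(pulses=((1.0, 0.8), (1.85, 0.8)))
        ev = detect_events(tr)
        assert ev.n_events == 1

    def test_clean_pulses_sensitivity_and_precision_one(self):
        truth = EventArray(np.array([1.0, 4.0, 7.0]), np.full(3, 1.0), 10.0)
        ev = detect_events(rectangular_pulse_trace())
        matched, n_det, n_truth = match_events(ev, truth, tol_s=0.03)
        assert matched == n_det == n_truth == 3

    def test_detected_events_satisfy_invariants(self):
        sim = simulate_calcium_trace(preset("ogb1", duration_s=300.0, seed=2))
        ev = detect_events(standard_preprocess(sim.trace))
        assert np.all(np.diff(ev.onsets_s) > 0)
        assert np.all(ev.ends_s[:-1] <= ev.onsets_s[1:] + 1e-9)
        assert np.all(ev.durations_s >= 0.6 - 1e-9)


class TestPostprocessRules:
    CFG = DetectionConfig()

    @staticmethod
    def _filtered(trace):
        return ema_filter(trace, 25.0)

    def test_gap_just_below_100ms_merges(self):
        tr = self._filtered(rectangular_pulse_trace(pulses=((1.0, 0.8), (1.85, 0.8))))
        raw = EventArray(np.array([1.0, 1.85]), np.array([0.8, 0.8]), 10.0)
        out = postprocess_events(raw, tr, self.CFG)
        assert out.n_events == 1

    def test_gap_exactly_100ms_does_not_merge(self):
        tr = self._filtered(rectangular_pulse_trace(pulses=((1.0, 0.8), (1.9, 0.8))))
        raw = EventArray(np.array([1.0, 1.9]), np.array([0.8, 0.8]), 10.0)
        out = postprocess_events(raw, tr, self.CFG)
        assert out.n_events == 2

    def test_500ms_wave_discarded_600ms_kept(self):
        tr = self._filtered(rectangular_pulse_trace(pulses=((1.0, 0.5), (4.0, 0.6))))
        raw = EventArray(np.array([1.0, 4.0]), np.array([0.5, 0.6]), 10.0)
        out = postprocess_events(raw, tr, self.CFG)
        assert out.n_events == 1
        assert out.onsets_s[0] == pytest.approx(4.0)

    def test_single_short_segment_yields_empty_array(self):
        tr = self._filtered(rectangular_pulse_trace(pulses=((1.0, 0.5),)))
        raw = EventArray(np.array([1.0]), np.array([0.5]), 10.0)
        out = postprocess_events(raw, tr, self.CFG)
        assert out.n_events == 0

    def test_weak_activity_below_intensity_floor_discarded(self):
        # a weak segment whose peak stays under the intensity floor (the
        # 90% cumulative-histogram point, capped at the onset threshold)
        # is removed even if handed in as a raw detection
        fs = 1000.0
        v = np.zeros(20_000)
        v[2000:3000] = 2.6
        v[8000:9000] = 2.6
        v[14_000: 14_800] = 1.0
        tr = self._filtered(make_trace(v, fs))
        raw = EventArray(np.array([2.0, 8.0, 14.0]),
                         np.array([1.0, 1.0, 0.8]), 20.0)
        out = postprocess_events(raw, tr, self.CFG)
        assert out.n_events == 2
        assert np.allclose(out.onsets_s, [2.0, 8.0])


class TestRefineTerminations:
    def test_noiseless_decay_terminates_at_2sigma_crossing(self):
        fs = 1000.0
        t = np.arange(int(6.0 * fs)) / fs
        v = np.where(t < 1.0, 0.0, 2.0 * np.exp(-(t - 1.0) / 0.5))
        tr = make_trace(v, fs)
        ev = EventArray(np.array([1.0]), np.array([0.3]), 6.0)
        out = refine_terminations(ev, tr, noise_sd=0.01)
        expected_end = 1.0 + 0.5 * np.log(2.0 / 0.02)
        assert out.ends_s[0] == pytest.approx(expected_end, abs=0.005)

    def test_correct_termination_unchanged(self):
        fs = 1000.0
        v = np.zeros(int(6.0 * fs))
        v[1000:2000] = 2.0
        tr = make_trace(v, fs)
        ev = EventArray(np.array([1.0]), np.array([1.0]), 6.0)
        out = refine_terminations(ev, tr, noise_sd=0.01)
        assert out.ends_s[0] == pytest.approx(2.0, abs=0.005)

    def test_event_abutting_session_end_clamped(self):
        fs = 1000.0
        v = np.zeros(int(3.0 * fs))
        v[1000:] = 2.0
        tr = make_trace(v, fs)
        ev = EventArray(np.array([1.0]), np.array([0.5]), 3.0)
        out = refine_terminations(ev, tr, noise_sd=0.01)
        assert out.ends_s[0] == pytest.approx(3.0, abs=0.01)

    def test_zero_noise_is_a_no_op(self):
        tr = rectangular_pulse_trace()
        ev = EventArray(np.array([1.0]), np.array([1.0]), 10.0)
        out = refine_terminations(ev, tr, noise_sd=0.0)
        assert np.array_equal(out.ends_s, ev.ends_s)


class TestBinarize:
    def test_overlap_convention(self):
        ev = EventArray(np.array([3.4]), np.array([1.2]), 10.0)
        sw = binarize_to_tr(ev, 1.0, 10)
        assert np.array_equal(np.flatnonzero(sw.bins), [3, 4])

    def test_empty_events_all_zero(self):
        sw = binarize_to_tr(EventArray.empty(10.0), 1.0, 10)
        assert sw.bins.sum() == 0

    def test_half_open_interval_exact_boundaries(self):
        ev = EventArray(np.array([2.0]), np.array([1.0]), 10.0)
        sw = binarize_to_tr(ev, 1.0, 10)
        assert np.array_equal(np.flatnonzero(sw.bins), [2])

    def test_events_beyond_session_rejected(self):
        ev = EventArray(np.array([9.5]), np.array([1.0]), 12.0)
        with pytest.raises(ValueError):
            binarize_to_tr(ev, 1.0, 10)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 5000))
    def test_marked_time_conserves_event_time_within_two_bins(self, seed):
        rng = np.random.default_rng(seed)
        onsets = np.sort(rng.uniform(0, 80, 5))
        keep = np.concatenate([[True], np.diff(onsets) > 4])
        onsets = onsets[keep]
        durs = rng.uniform(0.5, 2.5, onsets.size)
        ev = EventArray(onsets, durs, 100.0)
        sw = binarize_to_tr(ev, 1.0, 100)
        excess = sw.bins.sum() * 1.0 - durs.sum()
        assert 0 <= excess < 2.0 * ev.n_events


class TestEventFrequency:
    def test_ten_events_in_one_bin(self):
        ev = EventArray(np.linspace(2, 92, 10), np.full(10, 1.0), 100.0)
        freqs, epm = event_frequency(ev, 100.0)
        assert freqs[0] == pytest.approx(0.1)
        assert epm == pytest.approx(6.0)

    def test_empty_events_zero_frequency(self):
        freqs, epm = event_frequency(EventArray.empty(300.0), 100.0)
        assert np.all(freqs == 0) and epm == 0.0

    def test_session_shorter_than_bin_rejected(self):
        with pytest.raises(ValueError):
            event_frequency(EventArray.empty(50.0), 100.0)

    def test_simulated_session_rate_within_3se(self):
        sim = simulate_calcium_trace(preset("ogb1", duration_s=1800.0, seed=21))
        _, epm = event_frequency(sim.truth_events)
        se = np.sqrt(sim.truth_events.n_events) / 30.0
        assert abs(epm - 10.9) < 3 * se


class TestQuantifyWaveParams:
    @staticmethod
    def _ramp_decay_trace(rise_s=0.1, tau_s=0.5, amp=2.0, fs=1000.0):
        n = int(6.0 * fs)
        t = np.arange(n) / fs
        v = np.zeros(n)
        on = 2.0
        ramp = (t >= on) & (t < on + rise_s)
        v[ramp] = amp * (t[ramp] - on) / rise_s
        dec = t >= on + rise_s
        v[dec] = amp * np.exp(-(t[dec] - on - rise_s) / tau_s)
        return make_trace(v, fs)

    def test_closed_form_rise_duration_amplitude(self):
        tr = self._ramp_decay_trace()
        ev = EventArray(np.array([2.05]), np.array([1.5]), 6.0)
        q = quantify_wave_params(ev, tr)
        row = q.iloc[0]
        assert not row.flagged
        assert row.rise_time_ms == pytest.approx(50.0, abs=3.0)
        assert row.amplitude_dff == pytest.approx(2.0, abs=0.02)
        # duration = (rise + tau*ln2) - rise/2 for a linear ramp + exp decay
        assert row.duration_ms == pytest.approx(100 + 500 * np.log(2) - 50, abs=6.0)

    def test_flat_event_region_flagged_zero_amplitude(self):
        tr = make_trace(np.zeros(6000))
        ev = EventArray(np.array([2.0]), np.array([1.0]), 6.0)
        q = quantify_wave_params(ev, tr)
        assert q.iloc[0].flagged
        assert q.iloc[0].amplitude_dff == 0.0

    def test_too_short_event_skipped_with_warning(self):
        tr = self._ramp_decay_trace()
        ev = EventArray(np.array([2.05]), np.array([0.0005]), 6.0)
        with pytest.warns(UserWarning, match="shorter"):
            q = quantify_wave_params(ev, tr)
        assert q.iloc[0].flagged

    def test_recovers_planted_parameters_on_isolated_waves(self):
        cfg = preset("ogb1", duration_s=1200.0, event_rate_per_min=4.2,
                     refractory_s=12.0, seed=13)
        sim = simulate_calcium_trace(cfg)
        tr = standard_preprocess(sim.trace)
        q = quantify_wave_params(detect_events(tr), tr)
        ok = q[~q.flagged]
        assert len(ok) >= 70
        for col, planted in (
            ("rise_time_ms", sim.rise_times_ms.mean()),
            ("duration_ms", sim.durations_ms.mean()),
            ("amplitude_dff", sim.amplitudes_dff.mean()),
        ):
            se = ok[col].std() / np.sqrt(len(ok))
            assert abs(ok[col].mean() - planted) < 3.5 * se


class TestCalibrateThreshold:
    def test_needs_at_least_four_candidates(self):
        tr = rectangular_pulse_trace()
        with pytest.raises(ValueError, match=">=4"):
            calibrate_threshold(tr, None, [0.5, 0.7])

    def test_flat_curve_warns_and_returns_default(self):
        from swbold.simulate import BoldSimConfig, simulate_bold_session

        tr = make_trace(np.zeros(5000))
        bold = simulate_bold_session(
            BoldSimConfig(grid_shape=(3, 3, 1), n_volumes=60,
                          response_amplitude_pct=0.0, seed=0),
            EventArray.empty(60.0),
        ).session
        with pytest.warns(UserWarning, match="flat"):
            frac = calibrate_threshold(tr, bold, [0.3, 0.5, 0.7, 0.9])
        assert frac == 0.70

    def test_inflection_separates_noise_bumps_from_waves(self):
        from swbold.simulate import BoldSimConfig, simulate_bold_session

        fs = 1000.0
        T = 240.0
        rng = np.random.default_rng(5)
        v = rng.normal(0, 0.03, int(T * fs))
        wave_onsets = np.arange(5.0, T - 10, 8.0)
        for o in wave_onsets:
            i = int(o * fs)
            v[i: i + 1500] += 2.6 * np.exp(-np.arange(1500) / 700.0)
        for o in wave_onsets + 4.0:  # uncoupled weak bumps
            i = int(o * fs)
            v[i: i + 900] += 1.1 * np.exp(-np.arange(900) / 500.0)
        tr = make_trace(v, fs)
        truth = EventArray(wave_onsets, np.full(wave_onsets.size, 1.4), T)
        bold = simulate_bold_session(
            BoldSimConfig(grid_shape=(5, 5, 2), n_volumes=240,
                          noise_sd_pct=0.3, seed=6),
            truth,
        ).session
        frac = calibrate_threshold(tr, bold, [0.25, 0.4, 0.55, 0.7, 0.85])
        # bumps (1.1) vs waves (2.6): separation at ~1.1/ref
        assert 0.3 <= frac <= 0.7
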