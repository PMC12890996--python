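"""Beating-frequency pipeline: detrending, peak counting, FFT validation."""

import numpy as np
import pytest

from cmquant import contractility as ct
from cmquant.synthetic import BeatTraceSpec, gen_beat_stack, gen_beat_trace


def _trace(values, dt=0.5):
    values = np.asarray(values, dtype=float)
    return ct.IntensityTrace(times=np.arange(values.size) * dt, values=values)


class TestIntensityTrace:
    def test_rejects_nonuniform_grid(self):
        with pytest.raises(ValueError, match="uniform"):
            ct.IntensityTrace(times=np.array([0.0, 0.5, 1.2]), values=np.zeros(3))

    def test_rejects_nan(self):
        with pytest.raises(ValueError, match="non-finite"):
            _trace([1.0, np.nan, 2.0, 3.0])

    def test_duration_counts_full_frames(self):
        # 60 frames at 0.5 s cover a 30-s recording
        assert _trace(np.zeros(60)).duration_s == pytest.approx(30.0)


class TestDetrendNormalize:
    def test_constant_trace_gives_zeros(self):
        out = ct.detrend_normalize(_trace(np.full(80, 7.0)))
        assert np.all(out == 0.0)

    def test_linear_ramp_interior_residual_vanishes(self):
        # a symmetric moving average reproduces a line exactly away from edges
        tr = _trace(3.0 + 0.7 * np.arange(200) * 0.5)
        cfg = ct.DetrendConfig(window_s=5.0, weight_profile="triangular")
        window = int(round(5.0 / 0.5)) + 1
        base = ct._wma_baseline(tr.values, window, "triangular")
        resid = tr.values - base
        half = window // 2
        assert np.max(np.abs(resid[half:-half])) < 1e-6

    def test_output_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        tr = _trace(100 + rng.normal(0, 3, 300))
        out = ct.detrend_normalize(tr)
        assert abs(out.mean()) < 1e-9
        assert out.std() == pytest.approx(1.0, abs=1e-9)

    def test_sine_plus_ramp_recovers_sine(self):
        t = np.arange(240) * 0.5
        sine = np.sin(2 * np.pi * 0.5 * t)
        tr = _trace(50 + 0.2 * t + sine)
        out = ct.detrend_normalize(tr, ct.DetrendConfig(window_s=5.0))
        r = np.corrcoef(out, sine)[0, 1]
        assert r > 0.99

    def test_trace_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            ct.detrend_normalize(_trace(np.arange(10.0)), ct.DetrendConfig(window_s=8.0))

    def test_window_must_exceed_two_samples(self):
        with pytest.raises(ValueError, match="twice"):
            ct.detrend_normalize(_trace(np.arange(100.0)), ct.DetrendConfig(window_s=0.9))


class TestDetectBeats:
    def test_flat_series_no_peaks(self):
        assert ct.detect_beats(np.zeros(100), 0.5).size == 0

    def test_noiseless_sine_cycle_count(self):
        t = np.arange(120) * 0.5
        peaks = ct.detect_beats(np.sin(2 * np.pi * 0.5 * t), 0.5)
        assert peaks.size == 30

    def test_drifty_noisy_fixture_recovers_count(self):
        # 5x drift amplitude, 20% noise: peak count within one beat of truth
        spec = BeatTraceSpec(bpm_true=24, drift_amplitude=50.0, noise_sd=2.0,
                             irregularity_cv=0.0, seed=11)
        tr, beats = gen_beat_trace(spec)
        peaks = ct.detect_beats(ct.detrend_normalize(tr), tr.dt_s)
        assert abs(peaks.size - 24) <= 1

    def test_min_distance_keeps_higher_prominence(self):
        y = np.zeros(60)
        y[[20, 22]] = [1.0, 3.0]  # conflict at 1.0 s spacing: keep the taller
        out = ct.detect_beats(y, 0.5, ct.PeakConfig(min_prominence_sd=0.5,
                                                    min_distance_s=1.5))
        assert out.tolist() == [22]


class TestComputeBpm:
    @pytest.mark.parametrize(
        "n_peaks,duration,expected",
        [(15, 30.0, 30.0), (0, 30.0, 0.0), (90, 180.0, 30.0)],
    )
    def test_rate_arithmetic(self, n_peaks, duration, expected):
        assert ct.compute_bpm(np.arange(n_peaks), duration) == pytest.approx(expected)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            ct.compute_bpm(np.arange(3), 0.0)


class TestEstimateBpmFft:
    def test_pure_sine(self):
        t = np.arange(120) * 0.5
        bpm = ct.estimate_bpm_fft(np.sin(2 * np.pi * 0.5 * t), 0.5)
        assert abs(bpm - 30.0) <= ct.fft_bin_width_bpm(120, 0.5)

    def test_min_freq_excludes_slow_component(self):
        t = np.arange(120) * 0.5
        y = 1.0 * np.sin(2 * np.pi * 0.4 * t) + 0.3 * np.sin(2 * np.pi * 0.1 * t)
        bpm = ct.estimate_bpm_fft(y, 0.5, min_freq_hz=0.15)
        assert abs(bpm - 24.0) <= ct.fft_bin_width_bpm(120, 0.5)

    def test_flat_series_returns_zero(self):
        assert ct.estimate_bpm_fft(np.zeros(64), 0.5) == 0.0

    def test_seeded_fixture_within_one_bin(self):
        spec = BeatTraceSpec(bpm_true=36, seed=4)
        tr, _ = gen_beat_trace(spec)
        bpm = ct.estimate_bpm_fft(ct.detrend_normalize(tr), tr.dt_s)
        assert abs(bpm - 36.0) <= ct.fft_bin_width_bpm(tr.n, tr.dt_s)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            ct.estimate_bpm_fft(np.zeros(64), 0.0)


class TestAnalyzeTrace:
    def test_clean_thirty_bpm(self):
        spec = BeatTraceSpec(bpm_true=30, drift_amplitude=0, noise_sd=0,
                             irregularity_cv=0)
        tr, _ = gen_beat_trace(spec)
        res = ct.analyze_trace(tr)
        assert res.bpm_peaks == pytest.approx(30.0)
        assert res.agreement_ok
        assert not res.nyquist_warning

    def test_constant_trace_zero_bpm_agrees(self):
        tr = _trace(np.full(120, 9.0))
        res = ct.analyze_trace(tr)
        assert res.bpm_peaks == 0.0
        assert res.bpm_fft == 0.0
        assert res.agreement_ok

    def test_irregular_fixture_within_ten_percent(self):
        spec = BeatTraceSpec(bpm_true=30, irregularity_cv=0.3, seed=7)
        tr, _ = gen_beat_trace(spec)
        res = ct.analyze_trace(tr)
        assert abs(res.bpm_peaks - 30.0) <= 3.0

    def test_nyquist_warning_on_fast_rates(self):
        spec = BeatTraceSpec(bpm_true=52, drift_amplitude=0, noise_sd=0,
                             irregularity_cv=0)
        tr, _ = gen_beat_trace(spec)
        res = ct.analyze_trace(tr)
        assert res.nyquist_warning

    def test_bpm_identity_holds(self):
        spec = BeatTraceSpec(bpm_true=28, seed=9)
        tr, _ = gen_beat_trace(spec)
        res = ct.analyze_trace(tr)
        assert res.bpm_peaks == pytest.approx(60.0 * res.n_peaks / res.duration_s)

    @pytest.mark.parametrize("freq_hz", [0.01, 0.02, 0.03])
    def test_drift_robustness(self, freq_hz):
        # stage-wander drift at 10x the pulse amplitude, in the band the
        # moving average is designed to remove, changes the count by <= 1
        spec = BeatTraceSpec(bpm_true=30, drift_amplitude=0, noise_sd=0,
                             irregularity_cv=0)
        tr, _ = gen_beat_trace(spec)
        n0 = ct.analyze_trace(tr).n_peaks
        drifted = tr.values + 100.0 * np.sin(2 * np.pi * freq_hz * tr.times + 0.7)
        n1 = ct.analyze_trace(_trace(drifted)).n_peaks
        assert abs(n1 - n0) <= 1

    def test_amplitude_equivariance(self):
        spec = BeatTraceSpec(bpm_true=31, seed=5)
        tr, _ = gen_beat_trace(spec)
        base = ct.analyze_trace(tr)
        for c in (0.5, 3.0, 1000.0):
            scaled = ct.analyze_trace(_trace(tr.values * c))
            assert np.array_equal(scaled.peak_indices, base.peak_indices)
            assert scaled.bpm_fft == pytest.approx(base.bpm_fft)


class TestExtractRoiTrace:
    def test_constant_stack(self):
        stack = np.full((5, 8, 8), 7.0)
        tr = ct.extract_roi_trace(stack, (2, 2, 3, 3), 0.5)
        assert np.allclose(tr.values, 7.0)

    def test_frame_index_trace(self):
        stack = np.zeros((6, 8, 8))
        stack[:, 2:5, 2:5] = np.arange(6)[:, None, None]
        tr = ct.extract_roi_trace(stack, (2, 2, 3, 3), 0.5)
        assert np.allclose(tr.values, np.arange(6))

    def test_stack_fixture_matches_generator_within_rounding(self):
        spec = BeatTraceSpec(bpm_true=30, seed=2)
        stack, trace, _ = gen_beat_stack(spec, frame_shape=(32, 32),
                                         roi_bounds=(8, 8, 12, 12))
        extracted = ct.extract_roi_trace(stack, (8, 8, 12, 12), spec.dt_s)
        assert np.max(np.abs(extracted.values - trace.values)) <= 0.5 + 1e-9

    def test_roi_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ct.extract_roi_trace(np.zeros((3, 8, 8)), (5, 5, 6, 6), 0.5)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ct.extract_roi_trace(np.zeros((0, 8, 8)), (1, 1, 2, 2), 0.5)
        with pytest.raises(ValueError, match="empty"):
            ct.extract_roi_trace(np.zeros((3, 8, 8)), (1, 1, 0, 2), 0.5)
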