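"""Trace extraction, peak detection and kinetic parameter measurement."""

import numpy as np
import pytest
from scipy.signal import find_peaks

import calscan as cs
from calscan.errors import (
    AmplitudeUndefinedError,
    BoundsError,
    InsufficientDataError,
    TauUndefinedError,
)


def trace_of(values, ms_per_line=1.0, **kw):
    values = np.asarray(values, dtype=float)
    return cs.RegionTrace(values, np.arange(len(values)) * ms_per_line, **kw)


def triangle_train(centers, height, half_width, n, baseline=0.0):
    """Baseline plus identical triangular pulses (oracle-friendly trace)."""
    v = np.full(n, baseline)
    for c in centers:
        for k in range(-half_width, half_width + 1):
            if 0 <= c + k < n:
                v[c + k] = max(v[c + k], baseline + height * (1 - abs(k) / half_width))
    return v


class TestRegionTrace:
    def test_constant_image(self):
        img = cs.LineScanImage(np.full((16, 8), 3.0), ms_per_line=2.0)
        tr = cs.region_trace(img)
        np.testing.assert_array_equal(tr.values, 3.0)
        np.testing.assert_array_equal(tr.times_ms, np.arange(16) * 2.0)

    def test_two_pixel_mean(self):
        img = cs.LineScanImage(
            np.column_stack([np.zeros(10), np.full(10, 2.0)]), ms_per_line=1.0
        )
        np.testing.assert_array_equal(cs.region_trace(img).values, 1.0)

    def test_matches_per_row_mean_oracle(self, rng):
        a = rng.uniform(0, 50, (64, 32))
        img = cs.LineScanImage(a, ms_per_line=4.3)
        roi = cs.Roi(5, 20, 10, 60)
        tr = cs.region_trace(img, roi)
        np.testing.assert_allclose(tr.values, a[10:60, 5:20].mean(axis=1))
        np.testing.assert_allclose(tr.times_ms, np.arange(10, 60) * 4.3)


class TestDetectPeaks:
    def test_constant_trace_has_no_peaks(self):
        out = cs.detect_peaks(trace_of(np.ones(100)), cs.PeakParams(min_distance=5))
        assert out.size == 0

    def test_four_triangular_pulses(self):
        v = triangle_train([50, 150, 250, 350], 10.0, 20, 450)
        out = cs.detect_peaks(trace_of(v), cs.PeakParams(min_distance=70))
        np.testing.assert_array_equal(out, [50, 150, 250, 350])

    def test_close_pulses_thinned_keeping_taller(self):
        v = np.maximum(
            triangle_train([100], 10.0, 10, 300), triangle_train([130], 8.0, 10, 300)
        )
        out = cs.detect_peaks(trace_of(v), cs.PeakParams(min_distance=50))
        np.testing.assert_array_equal(out, [100])

    def test_invariant_to_constant_shift(self):
        v = triangle_train([40, 120, 200], 5.0, 15, 260)
        p = cs.PeakParams(min_distance=50)
        out0 = cs.detect_peaks(trace_of(v), p)
        out1 = cs.detect_peaks(trace_of(v + 123.4), p)
        np.testing.assert_array_equal(out0, out1)

    def test_minimum_distance_respected(self, rng):
        v = rng.normal(0, 1, 500).cumsum()
        v -= v.min() - 1.0
        out = cs.detect_peaks(trace_of(v), cs.PeakParams(min_distance=30))
        assert np.all(np.diff(out) >= 30)

    def test_peaks_are_local_maxima_above_threshold(self, rng):
        v = np.abs(rng.normal(0, 1, 400)).cumsum() % 37 + 1
        out = cs.detect_peaks(trace_of(v), cs.PeakParams(min_distance=10))
        for t in out:
            assert v[t] > v.mean()
            assert v[t] > v[t - 1] and v[t] >= v[t + 1]

    def test_agrees_with_scipy_find_peaks(self, rng):
        # smooth noisy trace without plateaus: scipy's height+distance
        # filtering implements the same thinning independently
        t = np.arange(600)
        v = 50 + 40 * np.sin(2 * np.pi * t / 80) + rng.normal(0, 1.0, 600)
        mine = cs.detect_peaks(trace_of(v), cs.PeakParams(min_distance=40))
        ref, _ = find_peaks(v, height=v.mean() + 1e-12, distance=40)
        np.testing.assert_array_equal(mine, ref)

    def test_short_trace_rejected(self):
        with pytest.raises(InsufficientDataError):
            cs.detect_peaks(trace_of([1, 2]), cs.PeakParams(min_distance=1))

    def test_threshold_k_raises_bar(self):
        v = triangle_train([30, 90], 2.0, 10, 120, baseline=10.0)
        lax = cs.detect_peaks(trace_of(v), cs.PeakParams(min_distance=20, threshold_k=0.0))
        strict = cs.detect_peaks(
            trace_of(v), cs.PeakParams(min_distance=20, threshold_k=5.0)
        )
        assert strict.size <= lax.size


class TestTransientBounds:
    def test_single_pulse_on_flat_baseline(self):
        v = triangle_train([50], 10.0, 20, 120, baseline=1.0)
        onset, end = cs.transient_bounds(trace_of(v), 50)
        assert onset == 30 and end == 70

    def test_unimodal_endpoint_fallback(self):
        v = np.concatenate([np.arange(50.0), np.arange(50.0)[::-1]])
        onset, end = cs.transient_bounds(trace_of(v), 49)
        assert (onset, end) == (0, len(v) - 1)

    def test_multi_pulse_matches_scan_oracle(self):
        v = triangle_train([50, 150, 250], 10.0, 20, 320, baseline=2.0)
        tr = trace_of(v)
        peaks = cs.detect_peaks(tr, cs.PeakParams(min_distance=70))
        for p in peaks:
            onset, end = cs.transient_bounds(tr, int(p), peaks)
            # oracle: walk outward while strictly descending
            j = p
            while j > 0 and v[j - 1] < v[j]:
                j -= 1
            k = p
            while k < len(v) - 1 and v[k + 1] < v[k]:
                k += 1
            assert (onset, end) == (j, k)

    def test_peak_at_start_rejected(self):
        with pytest.raises(BoundsError):
            cs.transient_bounds(trace_of([5, 4, 3, 2]), 0)


class TestRelativeAmplitude:
    def test_simple_ratio(self):
        tr = trace_of([1.0, 2.0, 3.0, 1.5])
        assert cs.relative_amplitude(tr, 2, 0) == pytest.approx(2.0)

    def test_degenerate_zero(self):
        tr = trace_of([1.0, 1.0, 1.0])
        assert cs.relative_amplitude(tr, 1, 0) == 0.0

    def test_zero_baseline_rejected(self):
        tr = trace_of([0.0, 5.0, 1.0])
        with pytest.raises(AmplitudeUndefinedError):
            cs.relative_amplitude(tr, 1, 0)

    def test_generator_ground_truth(self, control_noiseless):
        spec, img, truth = control_noiseless
        tr = cs.region_trace(img)
        peaks = cs.detect_peaks(tr, cs.PeakParams(min_distance=70))
        p = int(peaks[0])
        onset, _ = cs.transient_bounds(tr, p, peaks)
        # first transient rises from the true resting level F0 = 100 to 250
        assert cs.relative_amplitude(tr, p, onset) == pytest.approx(
            spec.amplitude, rel=1e-3
        )


class TestKinetics:
    def test_linear_ramp_geometry(self):
        v = np.concatenate([np.linspace(0, 100, 11), [50.0]])
        k = cs.kinetics(trace_of(v), 10, 0)
        assert k.time_to_peak_ms == pytest.approx(10.0)
        assert k.time_to_half_ms == pytest.approx(5.0)
        assert k.max_upstroke == pytest.approx(10.0)

    def test_instantaneous_rise(self):
        v = np.array([1.0, 1.0, 101.0, 50.0])
        k = cs.kinetics(trace_of(v), 2, 1)
        assert k.time_to_peak_ms == pytest.approx(1.0)
        assert k.time_to_half_ms == pytest.approx(0.5)  # interpolated inside the jump

    def test_half_time_never_exceeds_ttp(self, control_noiseless):
        _, img, _ = control_noiseless
        recs = cs.analyze_region(cs.region_trace(img), cs.PeakParams(min_distance=70))
        assert recs and all(r.time_to_half_ms <= r.time_to_peak_ms for r in recs)

    def test_calibration_equivariance(self):
        v = np.concatenate([np.linspace(0, 10, 6), np.linspace(10, 1, 10)])
        k1 = cs.kinetics(trace_of(v, ms_per_line=1.0), 5, 0)
        k2 = cs.kinetics(trace_of(v, ms_per_line=2.0), 5, 0)
        assert k2.time_to_peak_ms == 2 * k1.time_to_peak_ms
        assert k2.time_to_half_ms == 2 * k1.time_to_half_ms
        assert k2.max_upstroke == k1.max_upstroke / 2


class TestDecayTau:
    def test_closed_form_recovery(self):
        t = np.arange(0, 300.0)
        v = 10 + 90 * np.exp(-t / 50.0)
        fit = cs.decay_tau(trace_of(v), 0, len(v) - 1)
        assert fit.tau_ms == pytest.approx(50.0, rel=0.02)
        assert not fit.flagged

    def test_monotone_consistency(self):
        t = np.arange(0, 300.0)
        slow = cs.decay_tau(trace_of(10 + 90 * np.exp(-t / 50.0)), 0, 299)
        fast = cs.decay_tau(trace_of(10 + 90 * np.exp(-t / 25.0)), 0, 299)
        assert fast.tau_ms == pytest.approx(slow.tau_ms / 2, rel=0.02)

    def test_flat_segment_undefined(self):
        with pytest.raises(TauUndefinedError):
            cs.decay_tau(trace_of(np.full(50, 7.0)), 0, 49)

    def test_too_short_segment_undefined(self):
        with pytest.raises(TauUndefinedError):
            cs.decay_tau(trace_of([5.0, 4.0, 3.0]), 0, 2)

    def test_nonexponential_decay_flagged(self):
        t = np.arange(0, 200.0)
        v = 1.0 + np.maximum(0.0, 100.0 - t)  # linear decay, not exponential
        fit = cs.decay_tau(trace_of(v), 0, len(v) - 1)
        assert fit.flagged

    @pytest.mark.parametrize("tau", [20.0, 50.0, 100.0, 200.0])
    def test_recovery_under_noise(self, tau):
        # images at SNR 20 (noise sd = amplitude/20), 1 Hz pacing so the
        # decay runs to completion; median relative error < 5%
        errs = []
        for seed in range(3):
            spec = cs.SyntheticSpec(
                pattern="control", tau_ms=tau, pacing_hz=1.0, noise_scale=7.5,
                seed=seed,
            )
            img, _ = cs.generate_linescan(spec)
            recs = cs.analyze_region(
                cs.region_trace(img), cs.PeakParams(min_distance=200)
            )
            errs += [abs(r.tau_ms - tau) / tau for r in recs if np.isfinite(r.tau_ms)]
        assert np.median(errs) < 0.05


class TestAnalyzeRegion:
    def test_zero_noise_full_recovery(self, control_noiseless):
        spec, img, truth = control_noiseless
        recs = cs.analyze_region(cs.region_trace(img), cs.PeakParams(min_distance=70))
        assert len(recs) == truth.n_beats
        for r, line, amp in zip(recs, truth.full_peak_lines, truth.full_amplitudes):
            assert abs(r.peak_index - line) <= 1
            assert r.relative_amplitude == pytest.approx(amp, rel=0.01)
            assert r.tau_ms == pytest.approx(spec.tau_ms, rel=0.05)
            assert r.peak_value > r.baseline_value
            assert r.max_upstroke > 0

    def test_times_scale_with_calibration(self, control_noiseless):
        _, img, _ = control_noiseless
        from dataclasses import replace

        doubled = replace(img, ms_per_line=img.ms_per_line * 2)
        p = cs.PeakParams(min_distance=70)
        r1 = cs.analyze_region(cs.region_trace(img), p)
        r2 = cs.analyze_region(cs.region_trace(doubled), p)
        for a, b in zip(r1, r2):
            assert b.time_to_peak_ms == pytest.approx(2 * a.time_to_peak_ms)
            assert b.time_to_half_ms == pytest.approx(2 * a.time_to_half_ms)
            assert b.tau_ms == pytest.approx(2 * a.tau_ms)
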