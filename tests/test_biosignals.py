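import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from umiflow.biosignals import (
    BioSignal,
    CardiacTiming,
    FilterSpec,
    PressureCalibration,
    calibrate_pressure,
    compute_ptt,
    detect_r_peaks,
    extract_image_pulse,
    filter_ecg,
    normalize_ppg,
    per_cycle_peak_times,
    scale_to_reference,
    synchronize_clocks,
)
from umiflow.synthetic import lumen_area_waveform, render_bmode

FS = 200.0
T20 = np.arange(int(20 * FS)) / FS
CORE = slice(400, -400)  # away from the FIR edge transients


def _rms_db(x):
    return 20 * np.log10(max(np.sqrt(np.mean(x**2)), 1e-300) / np.sqrt(0.5))


class TestFilterChain:
    def test_mains_hum_removed_to_notch_spec(self):
        y = filter_ecg(BioSignal(np.sin(2 * np.pi * 50 * T20), FS, kind="ecg"))
        assert _rms_db(y.samples[CORE]) <= -90.0 + 3.0

    def test_baseline_drift_suppressed(self):
        y = filter_ecg(BioSignal(np.sin(2 * np.pi * 0.5 * T20), FS, kind="ecg"))
        assert _rms_db(y.samples[CORE]) <= -40.0

    @pytest.mark.parametrize("f0", [5.5, 10.0, 19.5])
    def test_passband_unity(self, f0):
        y = filter_ecg(BioSignal(np.sin(2 * np.pi * f0 * T20), FS, kind="ecg"))
        gain = np.sqrt(np.mean(y.samples[CORE] ** 2) / 0.5)
        assert abs(gain - 1.0) < 0.1

    def test_group_delay_compensated(self):
        x = np.sin(2 * np.pi * 10 * T20) * np.exp(-((T20 - 10.0) ** 2))
        y = filter_ecg(BioSignal(x, FS, kind="ecg")).samples
        lag = np.argmax(np.correlate(y, x, "full")) - (x.size - 1)
        assert lag == 0

    def test_linearity(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=T20.size), rng.normal(size=T20.size)
        fa = filter_ecg(BioSignal(a, FS, kind="ecg")).samples
        fb = filter_ecg(BioSignal(b, FS, kind="ecg")).samples
        fab = filter_ecg(BioSignal(2.0 * a - 0.7 * b, FS, kind="ecg")).samples
        np.testing.assert_allclose(fab, 2.0 * fa - 0.7 * fb, atol=1e-9)

    def test_zero_in_zero_out_and_fs_mismatch(self):
        y = filter_ecg(BioSignal(np.zeros(4000), FS, kind="ecg"))
        assert np.allclose(y.samples, 0.0)
        with pytest.raises(ValueError, match="fs"):
            filter_ecg(BioSignal(np.zeros(100), 100.0, kind="ecg"))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FilterSpec(highpass_stop=5.0, highpass_pass=2.0)
        with pytest.raises(ValueError, match="even"):
            FilterSpec(highpass_order=251)


class TestRPeaks:
    def test_impulse_train_rr(self):
        x = np.zeros(int(10 * FS))
        x[(np.arange(9) * FS + 100).astype(int)] = 1.0
        timing = detect_r_peaks(BioSignal(x, FS, kind="ecg"))
        assert np.allclose(timing.rr_intervals, 1.0, atol=1e-9)

    def test_short_rr_beat_reported(self):
        # one beat arrives 0.87 s after its predecessor
        beats = np.array([0.5, 1.5, 2.37, 3.37, 4.37])
        x = np.zeros(int(5 * FS))
        x[(beats * FS).astype(int)] = 1.0
        timing = detect_r_peaks(BioSignal(x, FS, kind="ecg"))
        assert timing.rr_intervals[1] == pytest.approx(0.87, abs=1e-6)

    def test_equal_maxima_tie_breaks_earlier(self):
        x = np.zeros(int(2 * FS))
        x[100] = 1.0
        x[110] = 1.0  # 50 ms later, equally tall
        timing = detect_r_peaks(BioSignal(x, FS, kind="ecg"), min_rr=0.4)
        assert timing.r_peak_times.size == 1
        assert timing.r_peak_times[0] == pytest.approx(0.5)

    def test_flat_signal_warns_empty(self):
        with pytest.warns(UserWarning, match="flat"):
            timing = detect_r_peaks(BioSignal(np.zeros(1000), FS, kind="ecg"))
        assert timing.r_peak_times.size == 0


class TestNormalizeCalibrate:
    def test_ramp_and_idempotence(self):
        sig = BioSignal(np.linspace(2, 4, 50), FS)
        n1 = normalize_ppg(sig)
        assert n1.samples.min() == 0.0 and n1.samples.max() == 1.0
        n2 = normalize_ppg(n1)
        np.testing.assert_allclose(n2.samples, n1.samples)

    @hyp_settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50), offset=st.floats(-100, 100))
    def test_affine_invariance(self, scale, offset):
        x = np.sin(np.linspace(0, 7, 200))
        a = normalize_ppg(BioSignal(x, FS)).samples
        b = normalize_ppg(BioSignal(scale * x + offset, FS)).samples
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_ppg(BioSignal(np.full(100, 3.0), FS))

    def test_calibration_spans_cuff_pressures(self):
        x = normalize_ppg(BioSignal(np.sin(np.linspace(0, 20, 500)), FS))
        p = calibrate_pressure(x, PressureCalibration(120.0, 80.0))
        assert p.samples.min() == pytest.approx(80.0)
        assert p.samples.max() == pytest.approx(120.0)

    def test_symmetric_triangle_mean(self):
        tri = np.abs(np.linspace(-1, 1, 401))
        p = calibrate_pressure(BioSignal(tri, FS), PressureCalibration(100.0, 60.0))
        assert p.samples.mean() == pytest.approx(80.0, abs=0.2)

    def test_invalid_calibration(self):
        with pytest.raises(ValueError):
            PressureCalibration(80.0, 120.0)
        with pytest.raises(ValueError, match="normalized"):
            calibrate_pressure(BioSignal(np.linspace(0, 2, 10), FS),
                               PressureCalibration(120.0, 80.0))

    def test_calibrate_normalize_idempotent(self):
        x = normalize_ppg(BioSignal(np.sin(np.linspace(0, 9, 300)), FS))
        cal = PressureCalibration(120.0, 80.0)
        p1 = calibrate_pressure(x, cal)
        p2 = calibrate_pressure(normalize_ppg(p1), cal)
        np.testing.assert_allclose(p1.samples, p2.samples, atol=1e-9)


class TestImagePulse:
    def test_constant_area_gives_constant_series(self):
        stack, prog = render_bmode(np.full(5, 900.0))
        pulse = extract_image_pulse(stack, 34.394)
        assert np.ptp(pulse.samples) <= 0.01 * prog[0]

    def test_programmed_area_tracked_without_speckle(self):
        t = np.arange(25) / 34.394
        areas = 1000.0 + 150.0 * np.sin(2 * np.pi * t / 0.933)
        stack, prog = render_bmode(areas)
        pulse = extract_image_pulse(stack, 34.394)
        rel = np.abs(pulse.samples - prog) / prog
        assert rel.mean() < 0.02

    def test_speckled_stack_correlates_with_programmed(self):
        t = np.arange(25) / 34.394
        areas = 1000.0 + 150.0 * np.sin(2 * np.pi * t / 0.933)
        stack, prog = render_bmode(areas, speckle_sigma=0.1, seed=4)
        pulse = extract_image_pulse(stack, 34.394)
        assert np.corrcoef(pulse.samples, prog)[0, 1] >= 0.99


class TestScaleToReference:
    def test_exact_affine_inverse(self):
        ppg = BioSignal(np.sin(np.linspace(0, 12, 600)) * 0.5 + 0.5, FS)
        img = BioSignal(2.0 * ppg.samples + 5.0, FS)
        scaled, (a, b) = scale_to_reference(img, ppg)
        assert a == pytest.approx(0.5, rel=1e-9)
        assert b == pytest.approx(-2.5, rel=1e-9)
        np.testing.assert_allclose(scaled.samples, ppg.samples, atol=1e-9)

    def test_identical_signals(self):
        ppg = BioSignal(np.sin(np.linspace(0, 12, 600)), FS)
        _, (a, b) = scale_to_reference(ppg, ppg)
        assert a == pytest.approx(1.0) and b == pytest.approx(0.0, abs=1e-9)

    def test_uncorrelated_noise_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        ppg = BioSignal(rng.normal(size=800), FS)
        img = BioSignal(rng.normal(size=800), FS)
        _, (a, b) = scale_to_reference(img, ppg)
        x = img.samples
        y = ppg.samples
        a_or = (np.mean(x * y) - x.mean() * y.mean()) / np.var(x)
        b_or = y.mean() - a_or * x.mean()
        assert a == pytest.approx(a_or, abs=1e-9)
        assert b == pytest.approx(b_or, abs=1e-9)
        assert abs(a) < 0.1 and b == pytest.approx(y.mean(), abs=0.1)

    def test_too_little_overlap_rejected(self):
        a = BioSignal(np.ones(10), FS, t0=0.0)
        b = BioSignal(np.ones(10), FS, t0=100.0)
        with pytest.raises(ValueError, match="overlap"):
            scale_to_reference(a, b)


class TestSynchronizeClocks:
    PEAKS = 0.2 + np.arange(8) * 0.933

    def test_device_offset_recovered(self):
        assert synchronize_clocks(self.PEAKS, self.PEAKS + 0.029) == 29

    def test_identical_trains_zero_shift(self):
        assert synchronize_clocks(self.PEAKS, self.PEAKS) == 0

    def test_noiseless_unbiased_across_offsets(self):
        for off in range(-490, 491, 35):
            rec = synchronize_clocks(self.PEAKS, self.PEAKS + off / 1000.0)
            assert rec == off

    def test_jitter_robustness_monte_carlo(self):
        hits = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            jit = rng.normal(0.0, 0.005, self.PEAKS.size)
            rec = synchronize_clocks(self.PEAKS, self.PEAKS + 0.029 + jit)
            hits += abs(rec - 29) <= 6
        assert hits / 200 >= 0.95

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError, match="peak pairs"):
            synchronize_clocks(self.PEAKS[:3], self.PEAKS[:3])


class TestPTT:
    def _pulse_with_foot(self, foot_lag, n_beats=4, period=1.0):
        # flat baseline then linear upstroke: the intersecting-tangents
        # construction recovers the programmed kink location
        t = np.arange(int(n_beats * period * FS)) / FS
        phase = (t - foot_lag) % period
        up = np.clip(phase / 0.15, 0, 1) * (phase < 0.15)
        decay = np.exp(-(phase - 0.15) / 0.25) * (phase >= 0.15)
        return BioSignal(up + decay, FS)

    def test_programmed_lag_recovered(self):
        pulse = self._pulse_with_foot(0.180)
        timing = CardiacTiming(np.arange(4) * 1.0)
        ptt = compute_ptt(timing, pulse)
        good = ptt[np.isfinite(ptt)]
        assert good.size >= 2
        assert np.abs(good - 0.180).max() < 0.02

    def test_foot_at_r_peak_gives_zero(self):
        pulse = self._pulse_with_foot(0.0)
        ptt = compute_ptt(CardiacTiming(np.arange(1, 3) * 1.0), pulse)
        good = ptt[np.isfinite(ptt)]
        assert good.size and np.abs(good).max() < 0.02

    def test_beat_without_upstroke_missing(self):
        flat = BioSignal(np.zeros(int(2 * FS)), FS)
        ptt = compute_ptt(CardiacTiming(np.array([0.2, 1.2])), flat)
        assert np.isnan(ptt).all()


def test_per_cycle_peaks_respect_r_windows():
    t = np.arange(int(4 * FS)) / FS
    x = np.sin(2 * np.pi * t)  # peaks at 0.25, 1.25, 2.25, ...
    peaks = per_cycle_peak_times(BioSignal(x, FS), r_peaks=np.arange(4) * 1.0)
    assert np.allclose(peaks, [0.25, 1.25, 2.25, 3.25], atol=0.01)
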