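import numpy as np
import pytest

from umiflow.biosignals import detect_r_peaks, filter_ecg, synchronize_clocks
from umiflow.solver import FluidProps, SolverSettings
from umiflow.synthetic import (
    InletWaveform,
    PPGOpticsParams,
    TwinScenario,
    generate_ecg,
    generate_ppg,
    generate_truth,
    inject_offset,
    lumen_area_waveform,
    render_bmode,
    sample_doppler,
    scenario_geometry,
    sync_recovery_trial,
)

SMALL = dict(nx=12, ny=24, dx=350e-6, dy=350e-6, diameter=4.2e-3, n_frames=4)


@pytest.fixture(scope="module")
def small_truth():
    scenario = TwinScenario(**SMALL)
    return scenario, generate_truth(scenario)


class TestDeterminism:
    def test_doppler_frames_bit_identical_under_seed(self, small_truth):
        scenario, truth = small_truth
        noisy = TwinScenario(**SMALL, noise_sigma=0.02, seed=42)
        f1 = sample_doppler(truth, noisy)
        f2 = sample_doppler(truth, noisy)
        for a, b in zip(f1, f2):
            assert np.array_equal(a.vm, b.vm)

    def test_bmode_and_ecg_bit_identical(self):
        areas = np.full(3, 700.0)
        s1, _ = render_bmode(areas, speckle_sigma=0.2, seed=9)
        s2, _ = render_bmode(areas, speckle_sigma=0.2, seed=9)
        assert np.array_equal(s1, s2)
        e1 = generate_ecg(np.arange(3) * 1.0, noise_sigma=0.1, seed=9)
        e2 = generate_ecg(np.arange(3) * 1.0, noise_sigma=0.1, seed=9)
        assert np.array_equal(e1.samples, e2.samples)


class TestDoppler:
    def test_noiseless_frames_equal_projected_truth(self, small_truth):
        scenario, truth = small_truth
        frames = sample_doppler(truth, scenario)
        from umiflow.assimilation import project_doppler

        vc = project_doppler(truth.fields[0], scenario.beam, truth.grid)
        np.testing.assert_array_equal(
            frames[0].vm[truth.grid.fluid], vc[truth.grid.fluid]
        )

    def test_noise_standard_deviation(self, small_truth):
        scenario, truth = small_truth
        sigma = 0.02
        noisy = TwinScenario(**SMALL, noise_sigma=sigma, seed=3)
        frames = sample_doppler(truth, noisy)
        clean = sample_doppler(truth, scenario)
        resid = np.concatenate([
            (a.vm - b.vm)[truth.grid.fluid] for a, b in zip(frames, clean)
        ])
        assert resid.size >= 500
        assert abs(resid.std() / sigma - 1.0) < 0.1

    def test_beam_perpendicular_to_flow_sees_nothing(self, small_truth):
        scenario, truth = small_truth
        # a beam along +y sees only v, which is ~0 in a straight channel
        along_y = TwinScenario(**SMALL, beam_angle_deg=0.0)
        frames = sample_doppler(truth, along_y)
        assert np.abs(frames[0].vm).max() < 1e-3


class TestTruth:
    def test_steady_scenario_matches_poiseuille(self):
        steady = TwinScenario(
            **SMALL | {"n_frames": 2},
            inlet=InletWaveform(mean=0.1, amplitudes=(0, 0, 0)),
        )
        truth = generate_truth(steady)
        grid = truth.grid
        mid = (grid.wall_lower_y[0] + grid.wall_upper_y[0]) // 2
        j = grid.nx // 2
        uc = 0.5 * (truth.fields[0].u[mid, j] + truth.fields[0].u[mid, j + 1])
        assert abs(uc / (1.5 * 0.1) - 1.0) < 0.03

    def test_inlet_flux_is_imposed_exactly(self, small_truth):
        scenario, truth = small_truth
        grid = truth.grid
        lo, hi = grid.wall_lower_y[0], grid.wall_upper_y[0]
        for k, f in enumerate(truth.fields):
            q = f.u[lo : hi + 1, 0].mean()
            assert q == pytest.approx(truth.inlet_velocity[k], rel=1e-12)

    def test_geometry_variants(self):
        for geom in ("straight", "tapered", "stenosed"):
            grid = scenario_geometry(TwinScenario(**SMALL | {"geometry": geom}))
            band = grid.wall_upper_y - grid.wall_lower_y + 1
            assert band.min() >= 3
        with pytest.raises(ValueError):
            scenario_geometry(TwinScenario(**SMALL | {"geometry": "helix"}))


class TestPPG:
    def test_constant_path_constant_intensity(self):
        optics = PPGOpticsParams(i0=2.0, epsilon=1.0, concentration=0.5)
        sig = generate_ppg(np.full(50, 2.0), optics, invert=False)
        np.testing.assert_allclose(sig.samples, 2.0 * np.exp(-1.0), rtol=1e-12)

    def test_unit_optical_depth(self):
        optics = PPGOpticsParams(i0=1.0, epsilon=1.0, concentration=1.0)
        sig = generate_ppg(np.ones(5), optics, invert=False)
        assert sig.samples[0] == pytest.approx(np.exp(-1.0))

    def test_intensity_antiphase_with_path(self):
        t = np.arange(400) / 200.0
        ell = 0.64 + 0.05 * np.sin(2 * np.pi * t)
        raw = generate_ppg(ell, invert=False)
        assert np.corrcoef(raw.samples, ell)[0, 1] <= -0.99
        inv = generate_ppg(ell, invert=True)
        assert np.corrcoef(inv.samples, ell)[0, 1] >= 0.99

    def test_invalid_path_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            generate_ppg(np.array([1.0, -0.1]))


class TestECG:
    def test_clean_beats_recovered(self):
        beats = 0.5 + np.arange(10) * 1.0
        ecg = generate_ecg(beats, fs=200.0)
        timing = detect_r_peaks(ecg)
        assert timing.r_peak_times.size == 10
        assert np.allclose(timing.rr_intervals, 1.0, atol=0.01)

    @pytest.mark.parametrize(
        "contamination",
        [dict(hum_amplitude=2.0), dict(drift_amplitude=1.0), dict(noise_sigma=0.05)],
    )
    def test_recovery_after_filtering_with_contamination(self, contamination):
        beats = 0.5 + np.arange(60) * 0.95
        ecg = generate_ecg(beats, fs=200.0, seed=1, **contamination)
        timing = detect_r_peaks(filter_ecg(ecg))
        # every injected beat found within 20 ms
        assert timing.r_peak_times.size == beats.size
        assert np.abs(timing.r_peak_times - beats).max() < 0.02


class TestOffsets:
    def test_zero_offset_identity(self):
        sig = generate_ppg(np.full(10, 0.6))
        out = inject_offset(sig, 0.0)
        assert out.t0 == sig.t0 and np.array_equal(out.samples, sig.samples)

    def test_29ms_offset_recovered_from_peak_trains(self):
        peaks = 0.2 + np.arange(8) * 0.933
        shifted = peaks + 0.029
        assert synchronize_clocks(peaks, shifted) == 29

    def test_out_of_range_offset_rejected(self):
        with pytest.raises(ValueError):
            inject_offset(generate_ppg(np.full(4, 0.6)), 2500.0)

    @pytest.mark.parametrize("seed", [3, 17])
    def test_end_to_end_recovery_with_jitter(self, seed):
        true_ms, rec_ms = sync_recovery_trial(seed)
        assert abs(rec_ms - true_ms) <= 10.0

    def test_noiseless_recovery_exact_to_coarse_step(self):
        for seed in range(10):
            true_ms, rec_ms = sync_recovery_trial(seed, jitter_ms=0.0)
            assert abs(rec_ms - true_ms) <= 1.5


def test_default_inlet_waveform_is_carotid_like():
    wf = InletWaveform()
    t = np.linspace(0, wf.period, 400, endpoint=False)
    u = wf(t)
    assert 0.05 < u.min() < 0.15
    assert 0.35 < u.max() < 0.55
    assert abs(np.mean(u) - wf.mean) < 1e-6


def test_lumen_area_waveform_periodic_positive():
    t = np.arange(0, 3.0, 0.005)
    a = lumen_area_waveform(t)
    assert a.min() > 0
    one = lumen_area_waveform(np.array([0.1]))
    again = lumen_area_waveform(np.array([0.1 + 0.933]))
    assert one == pytest.approx(again)
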