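"""Synthetic twin-experiment data generation.

Everything needed to exercise the whole pipeline with no external data:
ground-truth pulsatile channel flow from the package's own solver, Doppler
frame stacks with beam projection and additive noise, B-mode-like image
stacks of a pulsating lumen, Beer-Lambert PPG, template-based ECG with the
classic contaminants (mains hum, baseline drift, broadband noise), and
controlled clock offsets.

The default scenario mirrors a carotid acquisition: a straight channel of
6.4 mm diameter on a 36 x 86 grid (dx = 163 um, dy = 173 um), frames at
34.394 Hz, inlet velocities in roughly 0.1-0.5 m/s over a 0.933 s cardiac
period, biosignals at 200 Hz.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from umiflow.geometry import Grid2D, VesselGeometry, build_grid
from umiflow.assimilation import DopplerFrame, project_doppler
from umiflow.biosignals import BioSignal
from umiflow.solver import (
    BoundaryCondition,
    FlowField,
    FluidProps,
    SolverSettings,
    compute_wss,
    parabolic_profile,
    solve_steady,
    step,
)


def skewed_profile(y_rel: np.ndarray, skew: float = 0.7) -> np.ndarray:
    """A non-parabolic inlet shape: parabola times a linear skew factor."""
    return 6.0 * y_rel * (1.0 - y_rel) * (1.0 + skew * (y_rel - 0.5))


@dataclass(frozen=True)
class InletWaveform:
    """Carotid-like periodic inlet mean velocity: mean + 3 harmonics.

    U(t) = mean + sum_k a_k cos(2 pi k t / period + phi_k).  The defaults
    give a waveform sweeping roughly 0.10-0.47 m/s with a sharp systolic
    upstroke, the velocity range of a common carotid artery.
    """

    mean: float = 0.25
    amplitudes: tuple = (0.13, 0.055, 0.02)
    phases: tuple = (-np.pi / 2, np.pi / 2, 0.0)
    period: float = 0.933

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        u = np.full(t.shape, self.mean)
        for k, (a, ph) in enumerate(zip(self.amplitudes, self.phases), start=1):
            u = u + a * np.cos(2 * np.pi * k * t / self.period + ph)
        return u if u.shape else float(u)


@dataclass(frozen=True)
class TwinScenario:
    """A complete twin-experiment recipe.

    ``geometry``: "straight" | "tapered" | "stenosed" (stair-step channel
    variants of the given diameter).  ``beam_angle_deg`` is measured from
    the depth (y) axis.  ``noise_sigma`` is the i.i.d. Gaussian Doppler
    noise in m/s; ``clock_offset_ms`` shifts the measurement timestamps.
    A fixed ``seed`` makes every derived dataset bit-reproducible.
    """

    geometry: str = "straight"
    diameter: float = 6.4e-3
    nx: int = 36
    ny: int = 86
    dx: float = 163e-6
    dy: float = 173e-6
    inlet: InletWaveform = field(default_factory=InletWaveform)
    inlet_profile: str = "parabolic"  # "parabolic" | "skewed"
    frame_rate: float = 34.394
    n_frames: int = 35
    beam_angle_deg: float = 20.0
    noise_sigma: float = 0.0
    clock_offset_ms: float = 0.0
    biosignal_fs: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.frame_rate <= 0 or self.inlet.period <= 0:
            raise ValueError("rates and period must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def beam(self) -> np.ndarray:
        a = np.radians(self.beam_angle_deg)
        return np.array([np.sin(a), np.cos(a)])

    def profile_fn(self) -> Callable:
        return parabolic_profile if self.inlet_profile == "parabolic" else skewed_profile


@dataclass(frozen=True)
class PPGOpticsParams:
    """Beer-Lambert optics of the reflective PPG sensor.

    I = |I0| exp(-epsilon(lambda) C l): incident intensity I0 (arbitrary
    units), molar absorption coefficient epsilon (L/mol/cm) at the sensor
    wavelength lambda = 940 nm, hemoglobin molar concentration C (mol/L),
    optical path length l (cm) tied to the lumen size.
    """

    i0: float = 1.0
    epsilon: float = 1.1  # L/mol/cm, near-infrared hemoglobin scale
    concentration: float = 2.3e-3  # mol/L whole-blood hemoglobin
    wavelength_nm: float = 940.0

    def __post_init__(self):
        if min(self.i0, self.epsilon, self.concentration) <= 0:
            raise ValueError("optics parameters must be positive")


@dataclass
class TruthData:
    """Ground-truth run: fields, prescribed/imposed inlet U(t), WSS."""

    grid: Grid2D
    fields: list
    times: np.ndarray
    inlet_velocity: np.ndarray
    wss_lower: np.ndarray  # (n_frames, nx)


# ---------------------------------------------------------------------------
# geometry


def scenario_geometry(scenario: TwinScenario) -> Grid2D:
    """Stair-step channel grid for a scenario, vessel centered in depth."""
    n_rows = max(int(round(scenario.diameter / scenario.dy)), 3)
    lo = (scenario.ny - n_rows) // 2
    hi = lo + n_rows - 1
    x = np.arange(scenario.nx)
    if scenario.geometry == "straight":
        los = np.full(scenario.nx, lo)
        his = np.full(scenario.nx, hi)
    elif scenario.geometry == "tapered":
        # linear 15% narrowing toward the outlet
        shrink = np.round(0.15 * n_rows * x / max(scenario.nx - 1, 1) / 2).astype(int)
        los = lo + shrink
        his = hi - shrink
    elif scenario.geometry == "stenosed":
        # smooth bump narrowing the mid-channel by ~30%
        bump = 0.15 * n_rows * np.exp(-(((x - scenario.nx / 2) / (scenario.nx / 8)) ** 2))
        los = lo + np.round(bump).astype(int)
        his = hi - np.round(bump).astype(int)
    else:
        raise ValueError(f"unknown geometry '{scenario.geometry}'")
    return Grid2D(
        nx=scenario.nx, ny=scenario.ny, dx=scenario.dx, dy=scenario.dy,
        wall_lower_y=los, wall_upper_y=his,
    )


def channel_mask(
    height_px: int, width_px: int, band_px: int, center_row: Optional[int] = None
) -> np.ndarray:
    """A straight horizontal channel raster (testing convenience)."""
    mask = np.zeros((height_px, width_px), dtype=bool)
    c = height_px // 2 if center_row is None else center_row
    lo = c - band_px // 2
    mask[lo : lo + band_px, :] = True
    return mask


# ---------------------------------------------------------------------------
# ground-truth flow


def generate_truth(
    scenario: TwinScenario,
    props: FluidProps = FluidProps(),
    settings: Optional[SolverSettings] = None,
) -> TruthData:
    """Run the solver with the prescribed inlet waveform; outputs are truth.

    The first frame is a steady solution at U(0); subsequent frames are
    implicit steps at the measurement rate.
    """
    grid = scenario_geometry(scenario)
    settings = settings or SolverSettings(dt=scenario.dt)
    profile = scenario.profile_fn()
    times = np.arange(scenario.n_frames) * scenario.dt
    u_in = np.asarray(scenario.inlet(times))

    fields = [
        solve_steady(
            grid, BoundaryCondition(u_in[0], profile=profile), props, settings,
            tol=max(settings.residual_tol * 1e-2, 1e-5),
        )
    ]
    fields[0].t = times[0]
    for k in range(1, scenario.n_frames):
        prev2 = fields[k - 2] if k >= 2 else None
        fields.append(
            step(
                fields[-1],
                BoundaryCondition(u_in[k], profile=profile),
                props, settings, grid, field_prev=prev2,
            )
        )
    wss = np.stack([compute_wss(f, props, grid, "lower") for f in fields])
    return TruthData(
        grid=grid, fields=fields, times=times, inlet_velocity=u_in, wss_lower=wss
    )


def sample_doppler(
    truth: TruthData, scenario: TwinScenario, rng: Optional[np.random.Generator] = None
) -> list:
    """Doppler frames from truth: beam projection + Gaussian noise + offset.

    V_m = (truth velocity) . beam on the computational grid (the default
    acquisition has measurement resolution equal to the grid spacing),
    plus i.i.d. N(0, sigma^2) noise on valid points; timestamps carry the
    scenario clock offset.
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    frames = []
    for fld, t in zip(truth.fields, truth.times):
        vc = project_doppler(fld, scenario.beam, truth.grid)
        vm = np.where(truth.grid.fluid, vc, 0.0)
        if scenario.noise_sigma > 0:
            vm = vm + scenario.noise_sigma * rng.standard_normal(vm.shape)
            vm = np.where(truth.grid.fluid, vm, 0.0)
        frames.append(
            DopplerFrame(
                vm=vm, beam=scenario.beam,
                t=t + scenario.clock_offset_ms / 1000.0,
                valid=truth.grid.fluid.copy(),
            )
        )
    return frames


# ---------------------------------------------------------------------------
# B-mode image stack


def render_bmode(
    area_px: np.ndarray,
    image_size: tuple[int, int] = (128, 128),
    fs: float = 34.394,
    aspect: float = 0.7,
    speckle_sigma: float = 0.0,
    edge_px: float = 1.5,
    lumen_level: float = 0.15,
    tissue_level: float = 0.85,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Grayscale stack with a dark elliptical lumen of programmed area.

    ``area_px``: programmed lumen area (pixels) per frame; the ellipse has
    axis ratio ``aspect`` and a smooth edge of width ``edge_px``.
    Multiplicative speckle with relative sigma ``speckle_sigma`` emulates
    ultrasound texture.  Returns ``(stack, programmed_areas)``.
    """
    area_px = np.asarray(area_px, dtype=float)
    h, w = image_size
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2, w / 2
    frames = np.empty((area_px.size, h, w))
    for k, area in enumerate(area_px):
        b = np.sqrt(area * aspect / np.pi)  # semi-axis along y
        a = b / aspect
        if 2 * a >= w or 2 * b >= h:
            raise ValueError(f"frame {k}: lumen exceeds the image")
        r = np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)
        # smooth edge: 0 inside, 1 outside, over ~edge_px pixels
        edge = np.clip((r - 1.0) * (min(a, b) / edge_px) + 0.5, 0.0, 1.0)
        img = lumen_level + (tissue_level - lumen_level) * edge
        if speckle_sigma > 0:
            img = img * (1.0 + speckle_sigma * rng.standard_normal((h, w)))
        frames[k] = np.clip(img, 0.0, 1.3)
    return frames, area_px.copy()


# ---------------------------------------------------------------------------
# biosignals


def generate_ppg(
    path_length_cm: np.ndarray | Callable,
    optics: PPGOpticsParams = PPGOpticsParams(),
    fs: float = 200.0,
    duration: Optional[float] = None,
    invert: bool = True,
) -> BioSignal:
    """Beer-Lambert PPG from an optical path length waveform.

    I(t) = I0 exp(-epsilon C l(t)): a larger lumen (longer path through
    blood) absorbs more, so raw intensity is anti-phase with lumen size.
    With ``invert=True`` (default) the output is ``-I`` so the pulse is
    positive-going, tracking the lumen waveform.
    """
    if callable(path_length_cm):
        if duration is None:
            raise ValueError("duration required with a callable path length")
        t = np.arange(int(round(duration * fs))) / fs
        ell = np.asarray(path_length_cm(t), dtype=float)
    else:
        ell = np.asarray(path_length_cm, dtype=float)
    if (ell <= 0).any():
        raise ValueError("path length must be positive")
    intensity = optics.i0 * np.exp(-optics.epsilon * optics.concentration * ell)
    return BioSignal(-intensity if invert else intensity, fs=fs, kind="ppg")


def qrs_template(fs: float, width_s: float = 0.04) -> np.ndarray:
    """A minimal QRS-like spike: raised-cosine R wave with small side dips."""
    n = max(int(round(width_s * fs)) | 1, 3)
    t = np.linspace(-1, 1, n)
    r = 0.5 * (1 + np.cos(np.pi * t))
    dip = -0.12 * np.exp(-((np.abs(t) - 1.4) ** 2) / 0.1)
    return np.concatenate([dip[: n // 2], r, dip[n // 2 :]])


def generate_ecg(
    beat_times: np.ndarray,
    fs: float = 200.0,
    duration: Optional[float] = None,
    hum_amplitude: float = 0.0,
    hum_freq: float = 50.0,
    drift_amplitude: float = 0.0,
    drift_freq: float = 0.5,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> BioSignal:
    """Template ECG: QRS spikes at ``beat_times`` plus optional mains hum,
    baseline drift and broadband noise (all seeded)."""
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size > 1 and not (np.diff(beat_times) > 0).all():
        raise ValueError("beat times must be increasing")
    if duration is None:
        duration = beat_times[-1] + 0.5
    n = int(round(duration * fs))
    x = np.zeros(n)
    tpl = qrs_template(fs)
    half = tpl.size // 2
    for bt in beat_times:
        c = int(round(bt * fs))
        lo, hi = c - half, c - half + tpl.size
        s_lo, s_hi = max(lo, 0), min(hi, n)
        if s_lo < s_hi:
            x[s_lo:s_hi] += tpl[s_lo - lo : tpl.size - (hi - s_hi)]
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    if hum_amplitude:
        x = x + hum_amplitude * np.sin(2 * np.pi * hum_freq * t + 0.7)
    if drift_amplitude:
        x = x + drift_amplitude * np.sin(2 * np.pi * drift_freq * t + 0.2)
    if noise_sigma:
        x = x + noise_sigma * rng.standard_normal(n)
    return BioSignal(x, fs=fs, kind="ecg")


def inject_offset(obj, offset_ms: float):
    """Shift the clock of a BioSignal or DopplerFrame sequence by exactly
    ``offset_ms`` (timestamps only; data unchanged)."""
    if abs(offset_ms) > 2000:
        raise ValueError("offset outside +-2 s")
    dt = offset_ms / 1000.0
    if isinstance(obj, BioSignal):
        return BioSignal(obj.samples.copy(), obj.fs, obj.t0 + dt, obj.kind)
    out = []
    for fr in obj:
        out.append(
            DopplerFrame(
                vm=fr.vm.copy(), beam=fr.beam.copy(), t=fr.t + dt,
                valid=fr.valid.copy(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# area / path-length waveforms for the signal-chain twins


def lumen_area_waveform(
    t: np.ndarray,
    period: float = 0.933,
    base_area: float = 1000.0,
    pulse_fraction: float = 0.12,
) -> np.ndarray:
    """Carotid-like lumen-area pulse (pixel units): sharp systolic rise,
    dicrotic shoulder, slow diastolic decay."""
    def raw_shape(phase):
        rise = np.exp(-((phase - 0.18) ** 2) / (2 * 0.055**2))
        shoulder = 0.35 * np.exp(-((phase - 0.45) ** 2) / (2 * 0.09**2))
        decay = 0.15 * (1 - phase)
        return rise + shoulder + decay

    phase = (np.asarray(t, dtype=float) % period) / period
    # normalise against a dense reference cycle so the output is
    # independent of how the waveform is sampled
    ref = raw_shape(np.linspace(0.0, 1.0, 2048))
    shape = (raw_shape(phase) - ref.min()) / np.ptp(ref)
    return base_area * (1.0 + pulse_fraction * shape)


# ---------------------------------------------------------------------------
# end-to-end synchronization twin


def _per_cycle_peaks_dense(t: np.ndarray, x: np.ndarray, period: float) -> np.ndarray:
    """Per-cycle peak times of a waveform via cubic-spline refinement."""
    from scipy.interpolate import CubicSpline

    cs = CubicSpline(t, x)
    td = np.arange(t[0], t[-1], 1e-3)
    xd = cs(td)
    peaks = []
    n_cycles = int((t[-1] - t[0]) / period)
    for k in range(n_cycles):
        sel = (td >= t[0] + k * period) & (td < t[0] + (k + 1) * period)
        if sel.any():
            idx = np.flatnonzero(sel)
            peaks.append(td[idx[np.argmax(xd[idx])]])
    return np.array(peaks)


def sync_recovery_trial(
    seed: int,
    offset_range_ms: float = 300.0,
    jitter_ms: float = 5.0,
    n_cycles: int = 6,
    period: float = 0.933,
) -> tuple[float, float]:
    """One twin trial of the two-stage clock synchronization.

    A PPG waveform (Beer-Lambert, 200 Hz) and an image-pulse waveform
    (34.394 Hz) are generated from one lumen-area waveform; the image
    channel clock is offset by a uniform draw from +-``offset_range_ms``
    and its per-cycle peak times carry Gaussian jitter ``jitter_ms``.
    Stage 1 is the 1-ms exhaustive peak-time alignment over ``n_cycles``
    cycles; stage 2 refines the remainder with the 5-ms PU-loop linearity
    scan on a water-hammer beat pair carrying the residual misalignment.

    Returns ``(true_offset_ms, recovered_offset_ms)``.
    """
    from umiflow.biosignals import normalize_ppg, per_cycle_peak_times, synchronize_clocks
    from umiflow.wave import refine_sync

    rng = np.random.default_rng(seed)
    true_ms = float(rng.uniform(-offset_range_ms, offset_range_ms))

    dur = (n_cycles + 1.5) * period
    fs_ppg = 200.0
    t_ppg = np.arange(int(dur * fs_ppg)) / fs_ppg
    area = lumen_area_waveform(t_ppg, period=period)
    ell = 0.64 * np.sqrt(area / area.mean())  # optical path (cm) ~ diameter
    ppg = normalize_ppg(generate_ppg(ell, fs=fs_ppg))
    ppg_peaks = per_cycle_peak_times(ppg)

    fs_img = 34.394
    t_img = np.arange(int(dur * fs_img)) / fs_img
    img = lumen_area_waveform(t_img, period=period)
    img_peaks = _per_cycle_peaks_dense(t_img, img, period)
    img_peaks = img_peaks + true_ms / 1000.0 + rng.normal(0.0, jitter_ms / 1000.0, img_peaks.size)

    coarse = synchronize_clocks(ppg_peaks, img_peaks, n_cycles=n_cycles)

    # stage 2: the flow channel, corrected by the coarse estimate, still
    # lags the true clock by the residual r; a water-hammer beat pair
    # carries exactly that misalignment
    residual_s = (true_ms - coarse) / 1000.0
    fs = 200.0
    tb = np.arange(int(period * fs)) / fs
    u_beat = lumen_area_waveform(tb, period=period, base_area=0.223, pulse_fraction=0.9)
    p_beat = 80.0 + 250.0 * u_beat  # water hammer: P affine in U
    u_shifted = np.interp(tb - residual_s, tb, u_beat)
    from umiflow.biosignals import BioSignal as _BS

    fine = refine_sync(_BS(p_beat, fs, kind="pressure"), _BS(u_shifted, fs))
    recovered = float(coarse - fine)
    return true_ms, recovered


def sync_recovery_errors(n_trials: int = 100, seed: int = 0, **kwargs) -> np.ndarray:
    """Absolute recovery errors (ms) over seeded synchronization trials."""
    rng = np.random.default_rng(seed)
    trial_seeds = rng.integers(0, 2**31 - 1, size=n_trials)
    errs = []
    for s in trial_seeds:
        true_ms, rec_ms = sync_recovery_trial(int(s), **kwargs)
        errs.append(abs(rec_ms - true_ms))
    return np.array(errs)
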