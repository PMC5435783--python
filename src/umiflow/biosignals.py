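"""Pressure-measurement signal chain and clock synchronization.

This module carries a cardiovascular measurement session from raw signals to
a calibrated, synchronized pressure waveform:

- ECG conditioning: a 50 Hz notch (power-supply hum), a linear-phase FIR
  high-pass (baseline drift) and low-pass (myoelectric noise), with the
  filter group delay compensated so the output stays on the input clock;
- R-peak detection as the per-cycle ECG maximum;
- PPG normalization to [0, 1] and affine calibration to cuff systolic /
  diastolic pressures (the lumen diameter-pressure relation is treated as
  linear, so the pulse shape maps directly to mmHg);
- image-pulse extraction: per-frame lumen pixel area from B-mode-like
  grayscale stacks via Otsu thresholding and marker-based watershed
  segmentation;
- least-squares affine scaling of the image pulse onto the normalized PPG;
- clock alignment: an exhaustive 1-ms shift search minimising the mean
  squared difference of per-cycle peak times over six cardiac cycles;
- pulse transit time (PTT) from the ECG R peak to the pulse foot, the foot
  located by the intersecting-tangents construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage.filters import sobel, threshold_otsu
from skimage.segmentation import watershed


@dataclass
class BioSignal:
    """A uniformly sampled 1D biosignal.

    ``samples`` at rate ``fs`` (Hz) starting at clock time ``t0`` (s);
    ``kind`` in {"ecg", "ppg", "image_pulse", "pressure"}.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    kind: str = "ppg"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples must be finite")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray, kind: str | None = None) -> "BioSignal":
        return BioSignal(samples, self.fs, self.t0, kind or self.kind)


@dataclass(frozen=True)
class FilterSpec:
    """ECG conditioning chain specification (defaults: clinical setup).

    Notch: -90 dB at 50 Hz, 10 Hz bandwidth.  High-pass FIR, 250th order,
    stop-band edge 2 Hz, pass-band edge 5 Hz.  Low-pass FIR, 200th order,
    pass-band edge 20 Hz, stop-band edge 30 Hz.  All at fs = 200 Hz.
    Even FIR orders give integer group delays that are exactly compensated.
    """

    fs: float = 200.0
    notch_freq: float = 50.0
    notch_bandwidth: float = 10.0
    notch_attenuation_db: float = 90.0
    highpass_order: int = 250
    highpass_stop: float = 2.0
    highpass_pass: float = 5.0
    lowpass_order: int = 200
    lowpass_pass: float = 20.0
    lowpass_stop: float = 30.0

    def __post_init__(self):
        if not (0 < self.highpass_stop < self.highpass_pass):
            raise ValueError("high-pass edges must satisfy 0 < stop < pass")
        if not (0 < self.lowpass_pass < self.lowpass_stop):
            raise ValueError("low-pass edges must satisfy 0 < pass < stop")
        if self.highpass_order % 2 or self.lowpass_order % 2:
            raise ValueError("FIR orders must be even for integer delay compensation")


@dataclass(frozen=True)
class PressureCalibration:
    """Cuff systolic/diastolic pressures (mmHg) used to calibrate the PPG."""

    systolic: float
    diastolic: float

    def __post_init__(self):
        if not (self.systolic > self.diastolic > 0):
            raise ValueError("need systolic > diastolic > 0")


@dataclass
class CardiacTiming:
    """R-peak times (s), RR intervals (s) and optional per-beat PTT (s)."""

    r_peak_times: np.ndarray
    rr_intervals: np.ndarray = None
    ptt: np.ndarray | None = None

    def __post_init__(self):
        self.r_peak_times = np.asarray(self.r_peak_times, dtype=float)
        if self.rr_intervals is None:
            self.rr_intervals = np.diff(self.r_peak_times)
        if self.r_peak_times.size > 1 and not (np.diff(self.r_peak_times) > 0).all():
            raise ValueError("r_peak_times must be strictly increasing")


# ---------------------------------------------------------------------------
# ECG filtering and R peaks


def _fir_taps(spec: FilterSpec) -> tuple[np.ndarray, np.ndarray]:
    nyq = spec.fs / 2
    hp = signal.remez(
        spec.highpass_order + 1,
        [0, spec.highpass_stop, spec.highpass_pass, nyq],
        [0, 1],
        weight=[30, 1],
        fs=spec.fs,
    )
    lp = signal.remez(
        spec.lowpass_order + 1,
        [0, spec.lowpass_pass, spec.lowpass_stop, nyq],
        [1, 0],
        weight=[1, 30],
        fs=spec.fs,
    )
    return hp, lp


def _centered_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Linear-phase FIR with the integer group delay removed (edges are
    reflection-padded so the output stays aligned with the input clock)."""
    half = (taps.size - 1) // 2
    xp = np.pad(x, half, mode="reflect")
    y = signal.fftconvolve(xp, taps, mode="same")
    return y[half:-half] if half else y


def filter_ecg(raw: BioSignal, spec: FilterSpec = FilterSpec()) -> BioSignal:
    """Apply the notch + high-pass + low-pass chain, delay-compensated.

    Zero-phase notch (forward-backward second-order IIR) removes hum; the
    FIR stages are applied centered so the output remains on the input
    clock (cross-correlation peak with the input at lag 0).  The chain is
    linear, so superposition holds to numerical precision.
    """
    if abs(raw.fs - spec.fs) > 1e-9:
        raise ValueError(f"signal fs {raw.fs} does not match filter fs {spec.fs}")
    x = raw.samples
    b_n, a_n = signal.iirnotch(
        spec.notch_freq, spec.notch_freq / spec.notch_bandwidth, fs=spec.fs
    )
    y = signal.filtfilt(b_n, a_n, x) if x.size > 12 else x.copy()
    hp, lp = _fir_taps(spec)
    y = _centered_fir(y, hp)
    y = _centered_fir(y, lp)
    return raw.with_samples(y, kind="ecg")


def detect_r_peaks(ecg: BioSignal, min_rr: float = 0.4) -> CardiacTiming:
    """One R peak per cardiac cycle: local maxima at least ``min_rr`` apart;
    among equal candidates within a refractory window the earlier one is
    kept.  A flat signal yields an empty timing with a warning."""
    x = ecg.samples
    amp = np.ptp(x)
    if amp < 1e-12:
        warnings.warn("flat ECG signal: no R peaks detected")
        return CardiacTiming(np.array([]))
    peaks, _ = signal.find_peaks(x, prominence=0.3 * amp)
    if peaks.size == 0:
        warnings.warn("no R peaks found")
        return CardiacTiming(np.array([]))
    # greedy selection: highest first, equal heights broken toward earlier
    order = sorted(range(peaks.size), key=lambda i: (-x[peaks[i]], peaks[i]))
    min_gap = int(round(min_rr * ecg.fs))
    chosen: list[int] = []
    for i in order:
        if all(abs(peaks[i] - c) >= min_gap for c in chosen):
            chosen.append(peaks[i])
    chosen.sort()
    return CardiacTiming(ecg.t0 + np.array(chosen) / ecg.fs)


# ---------------------------------------------------------------------------
# PPG normalization and calibration


def normalize_ppg(ppg: BioSignal) -> BioSignal:
    """Affine map of the record onto [0, 1] via its min/max."""
    x = ppg.samples
    rng = np.ptp(x)
    if rng < 1e-12:
        raise ValueError("cannot normalize a constant signal")
    return ppg.with_samples((x - x.min()) / rng)


def calibrate_pressure(ppg_norm: BioSignal, cal: PressureCalibration) -> BioSignal:
    """Map a [0, 1] pulse onto [diastolic, systolic] mmHg (affine)."""
    x = ppg_norm.samples
    if x.min() < -1e-9 or x.max() > 1 + 1e-9:
        raise ValueError("input must be normalized to [0, 1]")
    p = cal.diastolic + (cal.systolic - cal.diastolic) * x
    return ppg_norm.with_samples(p, kind="pressure")


MMHG_TO_PA = 133.322


# ---------------------------------------------------------------------------
# image pulse


def _frame_lumen_area(img: np.ndarray) -> float:
    """Lumen pixel count of one grayscale frame (lumen darker than tissue).

    Otsu's threshold splits lumen from tissue; marker-based watershed on
    the gradient image places the boundary: the lumen marker is the darkest
    connected region, the background marker the bright region plus the
    frame border.
    """
    img = ndimage.gaussian_filter(np.asarray(img, dtype=float), 1.0)
    thr = threshold_otsu(img)
    lo = img.min() + 0.5 * (thr - img.min())
    hi = thr + 0.5 * (img.max() - thr)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[img > hi] = 1
    markers[0, :] = markers[-1, :] = 1
    markers[:, 0] = markers[:, -1] = 1
    dark = img < lo
    if not dark.any():
        return np.nan
    labels, n = ndimage.label(dark)
    sizes = ndimage.sum_labels(dark, labels, index=np.arange(1, n + 1))
    markers[labels == (1 + int(np.argmax(sizes)))] = 2
    seg = watershed(sobel(img), markers)
    area = int((seg == 2).sum())
    return float(area) if area > 0 else np.nan


def extract_image_pulse(frames: np.ndarray, fs: float) -> BioSignal:
    """Per-frame lumen pixel area of an image stack as a pulse waveform.

    ``frames``: (n, H, W) grayscale stack with the lumen darker than the
    surrounding tissue (ultrasound B-mode convention).  Frames where no
    lumen is found are interpolated from their neighbors with a warning.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be a (n, H, W) stack")
    areas = np.array([_frame_lumen_area(f) for f in frames])
    bad = ~np.isfinite(areas)
    if bad.all():
        raise ValueError("no vessel component found in any frame")
    if bad.any():
        warnings.warn(f"no vessel found in {bad.sum()} frame(s); interpolated")
        idx = np.arange(areas.size)
        areas[bad] = np.interp(idx[bad], idx[~bad], areas[~bad])
    return BioSignal(areas, fs=fs, kind="image_pulse")


def scale_to_reference(
    image_pulse: BioSignal, ppg_norm: BioSignal
) -> tuple[BioSignal, tuple[float, float]]:
    """Least-squares affine scaling of the image pulse onto the PPG.

    The image pulse is linearly resampled to the PPG rate over the
    overlapping time support; returns the scaled signal on the PPG clock
    and the coefficients ``(a, b)`` minimising sum(a x + b - ppg)^2.
    """
    t_lo = max(image_pulse.t0, ppg_norm.t0)
    t_hi = min(image_pulse.t[-1], ppg_norm.t[-1])
    tp = ppg_norm.t
    sel = (tp >= t_lo) & (tp <= t_hi)
    if sel.sum() < 2:
        raise ValueError("fewer than 2 overlapping samples")
    x = np.interp(tp[sel], image_pulse.t, image_pulse.samples)
    y = ppg_norm.samples[sel]
    A = np.stack([x, np.ones_like(x)], axis=1)
    (a, b), *_ = np.linalg.lstsq(A, y, rcond=None)
    scaled = BioSignal(a * x + b, ppg_norm.fs, tp[sel][0], kind="image_pulse")
    return scaled, (float(a), float(b))


# ---------------------------------------------------------------------------
# clock synchronization


def _pair_peaks(ref: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one nearest-neighbor pairing of two peak-time trains.

    Candidate pairs are accepted in order of increasing time distance;
    peaks left without a free partner stay unpaired.
    """
    cands = [
        (abs(o - r), i, j)
        for i, r in enumerate(ref)
        for j, o in enumerate(other)
        if abs(o - r) < 0.6  # beyond half a beat it is not the same cycle
    ]
    cands.sort()
    used_r: set[int] = set()
    used_o: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_r or j in used_o:
            continue
        used_r.add(i)
        used_o.add(j)
        pairs.append((ref[i], other[j]))
    if not pairs:
        return np.array([]), np.array([])
    out = np.array(sorted(pairs))
    return out[:, 0], out[:, 1]


def synchronize_clocks(
    ppg_peaks: np.ndarray,
    image_peaks: np.ndarray,
    shift_step_ms: float = 1.0,
    n_cycles: int = 6,
    search_ms: float = 500.0,
) -> int:
    """Clock offset (ms) of the image/ultrasound channel relative to PPG.

    Exhaustively scans integer multiples of ``shift_step_ms`` in
    +-``search_ms``, minimising the mean squared difference of paired peak
    times over the first ``n_cycles`` cycles.  Returns the shift ``s`` (ms)
    such that ``image_peaks - s/1000`` best aligns with ``ppg_peaks`` (the
    amount by which the image channel lags the PPG clock).  Ties prefer
    the smaller |s|.
    """
    ppg_peaks = np.asarray(ppg_peaks, dtype=float)
    image_peaks = np.asarray(image_peaks, dtype=float)
    if min(ppg_peaks.size, image_peaks.size) < n_cycles:
        raise ValueError(f"need at least {n_cycles} matched peak pairs")
    shifts = np.arange(-search_ms, search_ms + shift_step_ms / 2, shift_step_ms)
    best = None
    for s in shifts:
        try:
            ref, oth = _pair_peaks(ppg_peaks, image_peaks - s / 1000.0)
        except ValueError:
            continue  # colliding pairing at this candidate shift
        if ref.size < n_cycles:
            continue
        cost = float(np.mean((oth[:n_cycles] - ref[:n_cycles]) ** 2))
        key = (cost, abs(s))
        if best is None or key < best[0]:
            best = (key, s)
    if best is None:
        raise ValueError("no shift produced enough peak pairs")
    return int(round(best[1]))


def per_cycle_peak_times(pulse: BioSignal, r_peaks: np.ndarray | None = None) -> np.ndarray:
    """Peak time of each cardiac cycle of a pulse waveform.

    Cycles are delimited by the R-peak train when given; otherwise peaks
    are detected directly with a 0.4 s refractory constraint.
    """
    t = pulse.t
    x = pulse.samples
    if r_peaks is None or len(r_peaks) < 2:
        idx, _ = signal.find_peaks(
            x,
            prominence=0.3 * max(np.ptp(x), 1e-12),
            distance=max(int(0.4 * pulse.fs), 1),
        )
        return t[idx]
    out = []
    bounds = np.append(np.asarray(r_peaks, dtype=float), t[-1] + 1.0 / pulse.fs)
    for a, b in zip(bounds[:-1], bounds[1:]):
        sel = np.flatnonzero((t >= a) & (t < b))
        if sel.size:
            out.append(t[sel[np.argmax(x[sel])]])
    return np.array(out)


# ---------------------------------------------------------------------------
# pulse transit time


def _pulse_foot(t: np.ndarray, x: np.ndarray, fs: float) -> float:
    """Foot ("standing up") time by intersecting tangents: the horizontal
    baseline through the pre-upstroke minimum meets the tangent at the
    point of steepest upstroke slope.  NaN when no upstroke exists."""
    if x.size < 5 or np.ptp(x) < 1e-12:
        return np.nan
    dx = np.gradient(x, 1.0 / fs)
    i_peak = int(np.argmax(x))
    if i_peak < 2:
        return np.nan
    i_slope = int(np.argmax(dx[:i_peak]))
    slope = dx[i_slope]
    if slope <= 0:
        return np.nan
    i_min = int(np.argmin(x[: i_slope + 1]))
    baseline = x[i_min]
    t_foot = t[i_slope] - (x[i_slope] - baseline) / slope
    if not (t[0] - 1.0 / fs <= t_foot <= t[-1]):
        return np.nan
    return float(t_foot)


def compute_ptt(timing: CardiacTiming, pulse: BioSignal) -> np.ndarray:
    """Per-beat pulse transit time: pulse-foot time minus R-peak time.

    Beats whose foot cannot be located yield NaN.
    """
    r = timing.r_peak_times
    if r.size < 1:
        return np.array([])
    t = pulse.t
    bounds = np.append(r, t[-1] + 1.0 / pulse.fs)
    out = np.full(r.size, np.nan)
    for k in range(r.size):
        sel = (t >= bounds[k]) & (t < bounds[k + 1])
        if sel.sum() < 5:
            continue
        foot = _pulse_foot(t[sel], pulse.samples[sel], pulse.fs)
        if np.isfinite(foot):
            out[k] = foot - r[k]
    return out
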