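"""Wave intensity and PU-loop analysis.

Wave intensity WI = (dP/dt)(dU/dt), the product of the time derivatives of
blood pressure and cross-sectional mean velocity, identifies the direction
of arterial wave travel: positive during forward waves from the heart,
negative during backward (reflected) waves.  A positive WI peak with both
derivatives negative at end systole marks the flow-stopping "absorption"
wave.

The PU loop plots pressure against velocity over a beat.  By water-hammer
theory (dP = rho c dU along a unidirectional wave) the early-systolic limb
is a straight line when the pressure and flow channels are exactly
synchronized; a time offset between the channels bends it, and the bending
direction identifies the sign of the offset.  ``refine_sync`` exploits this
as a 5-ms-step synchronization refinement, maximising the linearity (R^2)
of the systolic limb.

Convention adopted for curvature labels (with P on the vertical axis):
delaying the pressure channel relative to the flow makes the systolic limb
sag below its chord ("concave"), advancing it makes the limb bulge above
("convex").  ``build_pu_loop`` classifies by the sign of the quadratic
coefficient of a parabola fitted over the systolic window, which the
package's synthetic water-hammer tests pin to this convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from umiflow.biosignals import BioSignal, _pulse_foot


@dataclass
class WaveIntensitySeries:
    """Paired derivatives and WI samples with per-sample wave labels.

    ``labels``: "forward" (dP/dt > 0, dU/dt > 0, WI above threshold),
    "backward" (WI below -threshold), "absorption" (both derivatives < 0,
    WI above threshold) or "none".  Labels are mutually exclusive.
    """

    t: np.ndarray
    dpdt: np.ndarray
    dudt: np.ndarray
    wi: np.ndarray
    labels: np.ndarray


@dataclass
class PULoop:
    """One-beat pressure-velocity trajectory with systolic-limb metrics."""

    p: np.ndarray
    u: np.ndarray
    systolic: slice
    r_squared: float
    curvature: str  # "straight" | "convex" | "concave"


#: labelling threshold as a fraction of the record's max |WI|
WI_PEAK_FRACTION = 0.05

#: |quadratic coefficient| (normalized coordinates) below which the
#: systolic limb counts as straight
CURVATURE_TOL = 0.05


def derivative(series: BioSignal, window: int = 5, polyorder: int = 2) -> BioSignal:
    """Smoothed first time derivative (local polynomial / Savitzky-Golay).

    Endpoints use one-sided polynomial fits.  ``window`` must be odd and
    no larger than the series.
    """
    x = series.samples
    if window > x.size:
        raise ValueError("smoothing window larger than the series")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    d = savgol_filter(
        x, window, polyorder, deriv=1, delta=1.0 / series.fs, mode="interp"
    )
    return series.with_samples(d)


def compute_wi(
    p: BioSignal, u: BioSignal, peak_fraction: float = WI_PEAK_FRACTION
) -> WaveIntensitySeries:
    """Pointwise wave intensity dP/dt * dU/dt with wave-type labels.

    ``p`` and ``u`` must be synchronized and sampled at a common rate.
    Units follow the inputs (mmHg/s times m/s^2 when P is in mmHg).
    """
    if p.samples.size != u.samples.size:
        raise ValueError("pressure and velocity series length mismatch")
    if abs(p.fs - u.fs) > 1e-9:
        raise ValueError("pressure and velocity series rate mismatch")
    dp = derivative(p).samples
    du = derivative(u).samples
    # flush derivative values at the round-off floor to exactly zero so a
    # constant channel yields WI = 0 with no labels
    for d, src in ((dp, p), (du, u)):
        dust = 64 * np.finfo(float).eps * src.fs * max(np.abs(src.samples).max(), 1.0)
        d[np.abs(d) < dust] = 0.0
    wi = dp * du
    thr = peak_fraction * np.max(np.abs(wi)) if np.any(wi) else np.inf
    labels = np.full(wi.size, "none", dtype=object)
    labels[(wi > thr) & (dp > 0) & (du > 0)] = "forward"
    labels[wi < -thr] = "backward"
    labels[(wi > thr) & (dp < 0) & (du < 0)] = "absorption"
    return WaveIntensitySeries(t=p.t, dpdt=dp, dudt=du, wi=wi, labels=labels)


def _systolic_window(u: BioSignal) -> slice:
    """Systolic limb of one beat: from the velocity foot to the peak."""
    x = u.samples
    t = u.t
    i_peak = int(np.argmax(x))
    foot_t = _pulse_foot(t[: i_peak + 1], x[: i_peak + 1], u.fs)
    if not np.isfinite(foot_t):
        raise ValueError("no systolic upstroke found")
    i_foot = int(np.searchsorted(t, foot_t))
    i_foot = min(max(i_foot, 0), max(i_peak - 2, 0))
    if i_peak - i_foot < 3:
        raise ValueError("systolic window too short")
    return slice(i_foot, i_peak + 1)


def build_pu_loop(p: BioSignal, u: BioSignal, beat: slice | None = None) -> PULoop:
    """PU loop over one beat with linearity and curvature of the systolic
    limb.

    The systolic window runs from the velocity foot (intersecting
    tangents) to the velocity peak.  ``r_squared`` is from a linear fit of
    P on U over that window; curvature is the sign of the quadratic
    coefficient of a parabola fit in min-max-normalized coordinates
    (|coef| < CURVATURE_TOL counts as straight): negative = "concave"
    (pressure sagging below the chord, delayed pressure channel),
    positive = "convex" (advanced pressure channel).
    """
    ps = p.samples[beat] if beat is not None else p.samples
    us = u.samples[beat] if beat is not None else u.samples
    if ps.size != us.size:
        raise ValueError("P and U length mismatch")
    ub = BioSignal(us, u.fs, 0.0, kind="ppg")
    sys_sl = _systolic_window(ub)
    uw = us[sys_sl]
    pw = ps[sys_sl]

    A = np.stack([uw, np.ones_like(uw)], axis=1)
    coef, *_ = np.linalg.lstsq(A, pw, rcond=None)
    resid = pw - A @ coef
    ss_tot = float(np.sum((pw - pw.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0

    # curvature in normalized coordinates so the tolerance is scale-free
    un = (uw - uw.min()) / max(np.ptp(uw), 1e-30)
    pn = (pw - pw.min()) / max(np.ptp(pw), 1e-30)
    c2 = float(np.polyfit(un, pn, 2)[0])
    if abs(c2) < CURVATURE_TOL:
        curvature = "straight"
    elif c2 > 0:
        curvature = "concave"  # limb sags below its chord: delayed pressure
    else:
        curvature = "convex"
    return PULoop(p=ps, u=us, systolic=sys_sl, r_squared=r2, curvature=curvature)


def _shift_signal(sig: BioSignal, advance_s: float) -> BioSignal:
    """Advance a signal in time by ``advance_s`` (interpolated, edge-held)."""
    t = sig.t
    return sig.with_samples(np.interp(t + advance_s, t, sig.samples))


def refine_sync(
    p: BioSignal,
    u: BioSignal,
    step_ms: float = 5.0,
    range_ms: float = 30.0,
) -> int:
    """PU-loop-based synchronization refinement.

    Scans pressure-channel advances in +-``range_ms`` at ``step_ms``
    steps, maximising the systolic-limb R^2; ties prefer the smaller
    |shift|.  Returns the advance (ms) to apply to the pressure channel:
    positive when the pressure channel was delayed.  Warns when the R^2
    profile is not unimodal over the scan.
    """
    shifts = np.arange(-range_ms, range_ms + step_ms / 2, step_ms)
    scores = []
    for s in shifts:
        try:
            loop = build_pu_loop(_shift_signal(p, s / 1000.0), u)
            scores.append(loop.r_squared)
        except ValueError:
            scores.append(-np.inf)
    scores = np.array(scores)
    if not np.isfinite(scores).any():
        raise ValueError("PU loop not computable at any candidate shift")
    best = scores.max()
    cand = shifts[scores >= best - 1e-12]
    s_best = cand[np.argmin(np.abs(cand))]
    finite = scores[np.isfinite(scores)]
    n_max = int(np.sum((finite[1:-1] > finite[:-2]) & (finite[1:-1] > finite[2:])))
    if n_max > 1:
        warnings.warn("R^2 profile not unimodal over the scan; returning argmax")
    return int(round(s_best))
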