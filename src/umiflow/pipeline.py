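"""End-to-end orchestration: sync -> assimilated run -> wave analysis.

``run_pipeline`` executes the full simultaneous-measurement analysis on a
dataset directory (or a self-generated synthetic twin when no inputs are
configured): ECG filtering and R peaks, image-pulse extraction and clock
alignment, the measurement-integrated flow run, and wave-intensity /
PU-loop analysis, emitting CSV series, a JSON summary, a JSONL log and a
seven-panel aligned figure (ECG, P, dP/dt, U, dU/dt, WSS, WI).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from umiflow import io as uio
from umiflow.assimilation import run_simulation
from umiflow.biosignals import (
    BioSignal,
    PressureCalibration,
    calibrate_pressure,
    detect_r_peaks,
    extract_image_pulse,
    filter_ecg,
    normalize_ppg,
    per_cycle_peak_times,
    scale_to_reference,
    synchronize_clocks,
)
from umiflow.config import RunConfig
from umiflow.solver import compute_wss, space_average_wss
from umiflow.synthetic import (
    TwinScenario,
    generate_ecg,
    generate_ppg,
    generate_truth,
    lumen_area_waveform,
    render_bmode,
    sample_doppler,
)
from umiflow.wave import build_pu_loop, compute_wi, derivative, refine_sync


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage '{stage}' failed: {err}")
        self.stage = stage


def _ensure_twin(cfg: RunConfig, out: Path, log) -> dict:
    """Load configured inputs, or generate the bundled default twin."""
    if cfg.frames_path and cfg.grid_path:
        return {
            "frames": uio.load_frames(cfg.frames_path),
            "grid": uio.load_grid(cfg.grid_path),
            "ppg": uio.load_signal(cfg.ppg_path) if cfg.ppg_path else None,
            "ecg": uio.load_signal(cfg.ecg_path) if cfg.ecg_path else None,
            "bmode": uio.load_bmode(cfg.bmode_path) if cfg.bmode_path else None,
            "truth": None,
        }
    log("generating default synthetic twin")
    scenario = TwinScenario(seed=cfg.seed, n_frames=20)
    truth = generate_truth(scenario, cfg.fluid_props(), cfg.solver_settings())
    frames = sample_doppler(truth, scenario)
    period = scenario.inlet.period
    dur = 7.5 * period
    t200 = np.arange(int(dur * 200.0)) / 200.0
    area = lumen_area_waveform(t200, period=period)
    ppg = generate_ppg(0.64 * np.sqrt(area / area.mean()), fs=200.0)
    beat_times = 0.18 * period + period * np.arange(int(dur / period))
    ecg = generate_ecg(beat_times, fs=200.0, duration=dur,
                       hum_amplitude=0.3, drift_amplitude=0.2, seed=cfg.seed)
    area_img = lumen_area_waveform(
        np.arange(int(dur * scenario.frame_rate)) / scenario.frame_rate, period=period
    )
    bmode, _ = render_bmode(area_img, fs=scenario.frame_rate,
                            speckle_sigma=0.08, seed=cfg.seed)
    uio.save_grid(out / "grid.h5", truth.grid)
    uio.save_frames(out / "frames.h5", frames)
    uio.save_signal(out / "ppg.csv", ppg)
    uio.save_signal(out / "ecg.csv", ecg)
    uio.save_bmode(out / "bmode.tif", bmode)
    return {"frames": frames, "grid": truth.grid, "ppg": ppg, "ecg": ecg,
            "bmode": bmode, "truth": truth}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute sync -> UMI/ordinary run -> WI and PU-loop analysis.

    Returns the summary dict (also written to ``summary.json``); artifacts
    land in ``cfg.out_dir``.  A stage failure aborts with the stage name,
    keeping artifacts written so far.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.jsonl"
    log_f = open(log_path, "a")

    def log(msg: str, **extra):
        rec = {"t_wall": time.time(), "msg": msg, **extra}
        log_f.write(json.dumps(rec) + "\n")
        log_f.flush()

    summary: dict = {"mode": cfg.mode, "gain": cfg.gain if cfg.mode == "umi" else 0.0}
    stage = "load"
    try:
        data = _ensure_twin(cfg, out, log)

        stage = "sync"
        shift_ms = None
        if data["ecg"] is not None:
            ecg_f = filter_ecg(data["ecg"])
            timing = detect_r_peaks(ecg_f)
            summary["n_beats"] = int(timing.r_peak_times.size)
        if data["ppg"] is not None and data["bmode"] is not None:
            ppg_n = normalize_ppg(data["ppg"])
            image_pulse = extract_image_pulse(data["bmode"], fs=34.394)
            scaled, (a, b) = scale_to_reference(image_pulse, ppg_n)
            shift_ms = synchronize_clocks(
                per_cycle_peak_times(ppg_n), per_cycle_peak_times(image_pulse)
            )
            summary["clock_shift_ms"] = shift_ms
            summary["image_pulse_scale"] = [a, b]
            log("synchronized", shift_ms=shift_ms)

        stage = "flow"
        result = run_simulation(
            data["frames"], data["grid"], cfg.fluid_props(), cfg.feedback_config(),
            cfg.solver_settings(), mode=cfg.mode,
            log=lambda m: log(m),
        )
        uio.save_error_series(out / "error_norm.csv", result)
        wss = np.stack(
            [compute_wss(f, cfg.fluid_props(), data["grid"], "lower") for f in result.fields]
        )
        uio.save_wss_series(out / "wss.csv", result.error_norm.t, wss)
        summary["mean_error_norm"] = float(result.error_norm.e.mean())
        summary["n_frames"] = len(result.fields)
        summary["no_feedback"] = cfg.mode == "ordinary"
        log("flow done", mean_e=summary["mean_error_norm"])

        stage = "wave"
        fs = 200.0
        t_u = result.error_norm.t
        t200 = np.arange(int(t_u[-1] * fs) + 1) / fs
        u200 = np.interp(t200, t_u, result.inlet_velocity)
        u_sig = BioSignal(u200, fs)
        if data["ppg"] is not None:
            ppg_n = normalize_ppg(data["ppg"])
            cal = PressureCalibration(cfg.systolic_mmhg, cfg.diastolic_mmhg)
            p_sig = calibrate_pressure(ppg_n, cal)
            p_win = BioSignal(p_sig.samples[: u200.size], fs, kind="pressure")
        else:  # water-hammer surrogate from the inflow itself
            p_win = BioSignal(80.0 + 160.0 * u200, fs, kind="pressure")
        wi = compute_wi(p_win, u_sig)
        fb_cols = cfg.feedback_config().domain_mask(data["grid"]).any(axis=0)
        j0, j1 = np.flatnonzero(fb_cols)[[0, -1]]
        wss_avg = np.array([space_average_wss(w, (j0, j1 + 1)) for w in wss])
        try:
            loop = build_pu_loop(p_win, u_sig)
            refined = refine_sync(p_win, u_sig)
            summary["pu_loop"] = {
                "r_squared": loop.r_squared,
                "curvature": loop.curvature,
                "refined_shift_ms": refined,
            }
        except ValueError as err:
            summary["pu_loop"] = {"error": str(err)}
        np_save = np.stack([wi.t, wi.dpdt, wi.dudt, wi.wi], axis=1)
        header = "t,dPdt,dUdt,WI"
        np.savetxt(out / "wi.csv", np_save, delimiter=",", header=header, comments="")
        summary["wi_peak"] = float(np.max(wi.wi))

        stage = "report"
        _panel_figure(out / "panels.png", data, result, p_win, u_sig, wi, wss_avg)
        uio.save_json(out / "summary.json", summary)
        log("pipeline complete")
    except Exception as err:
        log("stage failed", stage=stage, error=str(err))
        log_f.close()
        raise PipelineError(stage, err) from err
    log_f.close()
    return summary


def _panel_figure(path, data, result, p_sig, u_sig, wi, wss_avg):
    """Fig-style aligned panels: ECG, P, dP/dt, U, dU/dt, WSS, WI."""
    fig, axes = plt.subplots(7, 1, figsize=(8, 12), sharex=True)
    if data["ecg"] is not None:
        ecg_f = filter_ecg(data["ecg"])
        axes[0].plot(ecg_f.t, ecg_f.samples, lw=0.8)
    axes[0].set_ylabel("ECG")
    axes[1].plot(p_sig.t, p_sig.samples, lw=0.8)
    axes[1].set_ylabel("P [mmHg]")
    axes[2].plot(p_sig.t, derivative(p_sig).samples, lw=0.8)
    axes[2].set_ylabel("dP/dt")
    axes[3].plot(u_sig.t, u_sig.samples, lw=0.8)
    axes[3].set_ylabel("U [m/s]")
    axes[4].plot(u_sig.t, derivative(u_sig).samples, lw=0.8)
    axes[4].set_ylabel("dU/dt")
    axes[5].plot(result.error_norm.t, wss_avg, lw=0.8)
    axes[5].set_ylabel("WSS [Pa]")
    axes[6].plot(wi.t, wi.wi, lw=0.8)
    axes[6].set_ylabel("WI")
    axes[6].set_xlabel("t [s]")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
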