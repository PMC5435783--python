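"""Run configuration: YAML schema, validation and defaults.

All physical quantities carry explicit unit suffixes in their key names so
mmHg/Pa and ms/s mixups surface at validation time.  Unknown keys are
rejected (strict mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import yaml

from umiflow.assimilation import FeedbackConfig
from umiflow.solver import FluidProps, SolverSettings


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Validated configuration for the full pipeline.

    Defaults mirror the reference carotid setup: K_v* = 500, dt = 29.075 ms
    (34.394 Hz frames), V_type = 0.39 m/s, U = 0.1 m/s, L = 6.4 mm.
    """

    frames_path: Optional[str] = None
    grid_path: Optional[str] = None
    ppg_path: Optional[str] = None
    ecg_path: Optional[str] = None
    bmode_path: Optional[str] = None
    out_dir: str = "umiflow_out"
    mode: str = "umi"
    gain: float = 500.0
    dt_ms: Optional[float] = None
    frame_rate_hz: Optional[float] = 34.394
    v_type_m_s: float = 0.39
    u_char_m_s: float = 0.1
    l_char_mm: float = 6.4
    rho_kg_m3: float = 1.0e3
    mu_pa_s: float = 4.0e-3
    residual_tol: float = 1.0e-2
    inlet_tol: float = 1.0e-3
    feedback_domain: tuple = (1.0 / 36.0, 29.0 / 36.0)
    systolic_mmhg: float = 120.0
    diastolic_mmhg: float = 80.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("umi", "ordinary"):
            raise ConfigError("mode must be 'umi' or 'ordinary'")
        if self.gain < 0:
            raise ConfigError("feedback gain must be non-negative")
        if self.dt_ms is None:
            if not self.frame_rate_hz or self.frame_rate_hz <= 0:
                raise ConfigError("either dt_ms or frame_rate_hz is required")
            self.dt_ms = 1000.0 / self.frame_rate_hz
        if self.dt_ms <= 0:
            raise ConfigError("dt must be positive")
        if self.systolic_mmhg <= self.diastolic_mmhg:
            raise ConfigError("systolic must exceed diastolic")
        for key in ("frames_path", "grid_path", "ppg_path", "ecg_path", "bmode_path"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise ConfigError(f"{key}: file not found: {val}")

    def solver_settings(self) -> SolverSettings:
        return SolverSettings(
            dt=self.dt_ms / 1000.0,
            residual_tol=self.residual_tol,
            u_char=self.u_char_m_s,
        )

    def feedback_config(self) -> FeedbackConfig:
        return FeedbackConfig(
            k_v_star=self.gain if self.mode == "umi" else 0.0,
            domain_x=tuple(self.feedback_domain),
            u_char=self.u_char_m_s,
            l_char=self.l_char_mm / 1000.0,
            rho=self.rho_kg_m3,
            v_type=self.v_type_m_s,
        )

    def fluid_props(self) -> FluidProps:
        return FluidProps(rho=self.rho_kg_m3, mu=self.mu_pa_s)


def validate_config(raw: dict | str | Path) -> RunConfig:
    """Normalize a configuration mapping (or YAML path) into a RunConfig.

    Fills defaults, derives dt from the frame rate when omitted, and
    rejects unknown keys.
    """
    if not isinstance(raw, dict):
        text = Path(raw).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except (TypeError, ValueError) as err:
        if isinstance(err, ConfigError):
            raise
        raise ConfigError(str(err)) from err
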