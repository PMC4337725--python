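"""Run configuration: validated YAML schema, defaults, and seed derivation.

Every analysis default equals the study's printed value (300 bootstrap
resamples, α = 0.05, 1° interpolation step, 25 ms smoothing kernel); the
protocol and scene defaults are the stimulus parameters. A single master
seed is expanded into independent per-stage seeds through a deterministic
derivation so each pipeline stage is reproducible in isolation.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    trial_duration_ms: float = 1500.0
    ramp_duration_ms: float = 375.0
    plateau_duration_ms: float = 750.0
    translation_peak_cm_s: float = 24.0
    rotation_peak_deg_s: float = 17.0

    @model_validator(mode="after")
    def _check_timing(self):
        if abs(2 * self.ramp_duration_ms + self.plateau_duration_ms
               - self.trial_duration_ms) > 1e-9:
            raise ValueError("2*ramp + plateau must equal trial duration")
        return self


class SceneConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "cloud"
    near_clip_cm: float = 25.0
    far_clip_cm: float = 125.0
    plane_start_cm: float = 45.0
    viewing_distance_cm: float = 30.0
    screen_cm: float = 60.0
    grid_resolution: int = 33

    @model_validator(mode="after")
    def _check(self):
        if self.kind not in ("cloud", "plane"):
            raise ValueError("scene kind must be 'cloud' or 'plane'")
        if self.near_clip_cm >= self.far_clip_cm:
            raise ValueError("near_clip must be less than far_clip")
        return self


class PopulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_neurons: int = Field(default=72, ge=1)
    preference_range_deg: tuple[float, float] = (0.0, 360.0)
    amplitude_range_sps: tuple[float, float] = (30.0, 80.0)
    k: float = Field(default=3.0, gt=0)
    c_rp_range: tuple[float, float] = (1.0, 1.0)
    c_sp_range: tuple[float, float] = (1.0, 1.0)
    frame_weight: float = Field(default=1.0, ge=0.0, le=1.0)
    baseline_sps: float = Field(default=5.0, ge=0.0)
    rotation_amp_sps: float = Field(default=10.0, ge=0.0)
    rotation_rho: float = Field(default=0.5, ge=-1.0, le=1.0)
    gain_range: tuple[float, float] = (0.66, 1.33)
    offset_range: tuple[float, float] = (0.0, 40.0)
    repetitions: int = Field(default=5, ge=1)
    deformation_mode: str = "peak_shift"

    @model_validator(mode="after")
    def _check(self):
        if self.deformation_mode not in ("peak_shift", "geometric"):
            raise ValueError("deformation_mode must be 'peak_shift' or 'geometric'")
        for name in ("c_rp_range", "c_sp_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.2):
                raise ValueError(f"{name} must lie within [0, 1.2]")
        return self


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_boot: int = Field(default=300, ge=0)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    interp_step_deg: float = Field(default=1.0, gt=0.0)
    search_window_deg: int = Field(default=90, ge=1)
    kernel_sigma_ms: float = Field(default=25.0, gt=0.0)
    shift_mode: str = "signed"
    validation_k: float = Field(default=3.0, gt=0)
    validation_sets: int = Field(default=10, ge=1)

    @model_validator(mode="after")
    def _check(self):
        if self.shift_mode not in ("signed", "absolute"):
            raise ValueError("shift_mode must be 'signed' or 'absolute'")
        return self


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    protocol: ProtocolConfig = ProtocolConfig()
    scene: SceneConfig = SceneConfig()
    population: PopulationConfig = PopulationConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    seed: int = Field(default=0, ge=0, lt=2**31)

    def to_protocol_spec(self):
        from .protocol import ProtocolSpec

        return ProtocolSpec(
            trial_duration_ms=self.protocol.trial_duration_ms,
            ramp_duration_ms=self.protocol.ramp_duration_ms,
            plateau_duration_ms=self.protocol.plateau_duration_ms,
            translation_peak_cm_s=self.protocol.translation_peak_cm_s,
            rotation_peak_deg_s=self.protocol.rotation_peak_deg_s,
        )


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration; None → all defaults.

    Unknown keys are rejected with the offending key path in the error.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31.

    Derived from the master seed and a CRC32 of the stage name through a
    SeedSequence, so stages are statistically independent and individually
    reproducible.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))
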