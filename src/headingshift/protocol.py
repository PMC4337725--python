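"""Experimental protocol: trapezoidal velocity profiles and condition tables.

A trial lasts 1500 ms. Translation and yaw-rotation speeds follow a
trapezoid: linear ramp up over the first 375 ms, constant plateau for the
middle 750 ms, linear ramp down over the last 375 ms. Peak speeds are
24 cm/s (translation) and 17 deg/s (rotation). Eight headings at 45° steps
are combined with five main condition types (pure translation, real pursuit
left/right, simulated pursuit left/right) plus eight controls, giving 48
unique stimulus conditions per block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Display update rate (Hz) used to discretize all schedules.
FRAME_RATE_HZ = 60.0

#: Analysis window bounds (ms): the constant-velocity plateau.
PLATEAU_START_MS = 375.0
PLATEAU_END_MS = 1125.0

ROTATION_DIRECTIONS = ("left", "right")

#: Main (heading-bearing) condition labels.
MAIN_CONDITIONS = ("translation_only", "RP_left", "RP_right", "SP_left", "SP_right")

#: Control conditions: three pure-rotation pairs plus two fixation controls.
CONTROL_CONDITIONS = (
    "pursuit_dark_left",
    "pursuit_dark_right",
    "pursuit_static_left",
    "pursuit_static_right",
    "sim_rotation_left",
    "sim_rotation_right",
    "blank",
    "static_fix",
)


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and kinematics of one trial block."""

    trial_duration_ms: float = 1500.0
    ramp_duration_ms: float = 375.0
    plateau_duration_ms: float = 750.0
    translation_peak_cm_s: float = 24.0
    rotation_peak_deg_s: float = 17.0
    headings_deg: tuple[float, ...] = tuple(float(h) for h in range(0, 360, 45))
    pursuit_start_offset_deg: float = 9.5

    def __post_init__(self) -> None:
        if not np.isclose(
            2 * self.ramp_duration_ms + self.plateau_duration_ms,
            self.trial_duration_ms,
        ):
            raise ValueError("2*ramp + plateau must equal trial duration")
        wrapped = [h % 360.0 for h in self.headings_deg]
        if len(set(wrapped)) != len(wrapped):
            raise ValueError("headings must be unique modulo 360")

    @property
    def plateau_window_ms(self) -> tuple[float, float]:
        return (self.ramp_duration_ms, self.ramp_duration_ms + self.plateau_duration_ms)

    def time_grid_ms(self) -> np.ndarray:
        """Trial time samples at the display frame rate (inclusive of t=0)."""
        dt = 1000.0 / FRAME_RATE_HZ
        n = int(round(self.trial_duration_ms / dt))
        return np.arange(n + 1) * dt


@dataclass(frozen=True)
class Condition:
    """One stimulus condition: a label plus heading for non-controls."""

    label: str
    heading_deg: float | None = None
    rotation_dir: str | None = None  # None for translation_only and fixation controls

    def __post_init__(self) -> None:
        if self.is_control and self.heading_deg is not None:
            raise ValueError("control conditions carry no heading")
        if not self.is_control and self.heading_deg is None:
            raise ValueError("non-control conditions require a heading")

    @property
    def is_control(self) -> bool:
        base = self.label.rsplit("_", 1)[0] if "_" in self.label else self.label
        return self.label in CONTROL_CONDITIONS or base in (
            "pursuit_dark",
            "pursuit_static",
            "sim_rotation",
        ) or self.label in ("blank", "static_fix")

    @property
    def condition_type(self) -> str:
        """'translation', 'RP', 'SP', or 'control'."""
        if self.is_control:
            return "control"
        if self.label == "translation_only":
            return "translation"
        return self.label.split("_", 1)[0]


def trapezoid(t_ms, peak: float, spec: ProtocolSpec = ProtocolSpec()):
    """Instantaneous speed at time ``t_ms`` for a trapezoidal profile.

    Linear ramp on [0, ramp], constant ``peak`` on the plateau, linear ramp
    down on [trial-ramp, trial]. Vectorized over ``t_ms``.
    """
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0) or np.any(t > spec.trial_duration_ms):
        raise ValueError("t outside trial")
    ramp, total = spec.ramp_duration_ms, spec.trial_duration_ms
    up = t / ramp
    down = (total - t) / ramp
    v = peak * np.clip(np.minimum(up, down), 0.0, 1.0)
    return float(v) if np.isscalar(t_ms) else v


def trapezoid_integral(t_ms, peak: float, spec: ProtocolSpec = ProtocolSpec()):
    """Displacement ∫0..t v dτ for the trapezoid, in peak-units·seconds.

    Closed form; over a whole trial it equals peak·(plateau + ramp) seconds,
    e.g. 24 cm/s gives a 27 cm excursion.
    """
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0) or np.any(t > spec.trial_duration_ms):
        raise ValueError("t outside trial")
    ramp = spec.ramp_duration_ms
    t_down = spec.trial_duration_ms - ramp  # start of the descending ramp
    # piecewise: quadratic ramp, linear plateau, quadratic tail
    s_ramp = 0.5 * np.minimum(t, ramp) ** 2 / ramp
    s_plateau = np.clip(np.minimum(t, t_down) - ramp, 0.0, None)
    tail = np.clip(t - t_down, 0.0, None)
    s_tail = tail - 0.5 * tail**2 / ramp
    s = peak * (s_ramp + s_plateau + s_tail) / 1000.0  # ms -> s
    return float(s) if np.isscalar(t_ms) else s


def enumerate_conditions(
    spec: ProtocolSpec = ProtocolSpec(), main_only: bool = False
) -> list[Condition]:
    """All unique stimulus conditions for one block (48 by default)."""
    conds: list[Condition] = []
    for label in MAIN_CONDITIONS:
        rot = label.split("_", 1)[1] if "_" in label else None
        for h in spec.headings_deg:
            conds.append(Condition(label=label, heading_deg=h % 360.0, rotation_dir=rot))
    if not main_only:
        for label in CONTROL_CONDITIONS:
            rot = label.rsplit("_", 1)[1] if label.endswith(("left", "right")) else None
            conds.append(Condition(label=label, rotation_dir=rot))
    return conds


def pursuit_target_trajectory(
    direction: str, t_ms, spec: ProtocolSpec = ProtocolSpec()
):
    """Pursuit-target azimuth (deg from screen center) over the trial.

    A rightward trial starts with the target ``pursuit_start_offset_deg`` to
    the LEFT of center and sweeps rightward with the rotation trapezoid;
    leftward trials mirror it. Positive = right of center.
    """
    if direction not in ROTATION_DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    excursion = trapezoid_integral(t_ms, spec.rotation_peak_deg_s, spec)
    sign = 1.0 if direction == "right" else -1.0
    start = -sign * spec.pursuit_start_offset_deg
    return start + sign * excursion


def rotation_angle_deg(direction: str, t_ms, spec: ProtocolSpec = ProtocolSpec()):
    """Integrated eye/camera yaw (deg) since trial start; rightward positive."""
    sign = 1.0 if direction == "right" else -1.0
    return sign * trapezoid_integral(t_ms, spec.rotation_peak_deg_s, spec)


def fp_distance_schedule(
    t_ms,
    spec: ProtocolSpec = ProtocolSpec(),
    start_distance_cm: float = 45.0,
):
    """Simulated fronto-parallel plane distance during forward approach.

    distance(t) = start − ∫ v(τ)dτ; 45 cm at onset, 18 cm at trial end with
    the default 24 cm/s trapezoid (27 cm total travel).
    """
    d = start_distance_cm - trapezoid_integral(t_ms, spec.translation_peak_cm_s, spec)
    if np.any(np.asarray(d) <= 0):
        raise ValueError("plane distance reaches zero within the trial")
    return d
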