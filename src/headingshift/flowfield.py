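"""Analytic optic-flow geometry under combined translation and yaw rotation.

Coordinates are right-handed and eye-centered: +X rightward, +Y upward,
+Z into the scene. Heading azimuth is measured in the horizontal plane with
0° = rightward, 90° = straight ahead, 180° = leftward, 270° = backward.
Positive yaw rate means a rightward eye rotation.

A scene point P = (X, Y, Z) projects onto a screen at viewing distance D as
(x, y) = (D·X/Z, D·Y/Z). Differentiating under simultaneous observer
translation T (so the point moves at −T relative to the eye) and yaw ω
(point motion −ω × P) gives the screen velocity. The translational term
scales as 1/Z while the rotational term is depth-independent — the geometric
fact behind depth-dependent FOE shifts, motion-parallax subtraction, and
dynamic-perspective cues.

FOE azimuths are reported in screen-linear degrees, i.e. the horizontal
screen offset divided by the viewing distance, converted from radians
(x/D·180/π). This matches how shifts were measured on the rendered display.
A true visual angle atan(x/D) is kept as a secondary field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .protocol import ProtocolSpec, fp_distance_schedule, trapezoid


@dataclass(frozen=True)
class SelfMotionState:
    """Observer translation speed/heading and yaw rate."""

    translation_speed_cm_s: float = 24.0
    heading_azimuth_deg: float = 90.0  # 90° = straight ahead
    yaw_rate_deg_s: float = 0.0  # positive = rightward rotation

    def __post_init__(self) -> None:
        if self.translation_speed_cm_s < 0:
            raise ValueError("translation speed must be non-negative")
        object.__setattr__(
            self, "heading_azimuth_deg", self.heading_azimuth_deg % 360.0
        )

    @property
    def translation_vector(self) -> np.ndarray:
        """(Tx, Ty, Tz) cm/s; horizontal-plane heading, so Ty = 0."""
        h = math.radians(self.heading_azimuth_deg)
        return self.translation_speed_cm_s * np.array([math.cos(h), 0.0, math.sin(h)])

    @property
    def yaw_rate_rad_s(self) -> float:
        return math.radians(self.yaw_rate_deg_s)


@dataclass(frozen=True)
class ScreenGeometry:
    """Flat projection screen facing the observer."""

    viewing_distance_cm: float = 30.0
    width_cm: float = 60.0
    height_cm: float = 60.0
    grid_resolution: int = 33

    def __post_init__(self) -> None:
        if self.viewing_distance_cm <= 0:
            raise ValueError("viewing distance must be positive")
        if self.grid_resolution < 1:
            raise ValueError("grid must be non-empty")

    @property
    def fov_deg(self) -> tuple[float, float]:
        d = self.viewing_distance_cm
        return (
            2 * math.degrees(math.atan(self.width_cm / (2 * d))),
            2 * math.degrees(math.atan(self.height_cm / (2 * d))),
        )

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Regular (x, y) screen sample grid in cm, meshgrid-indexed 'xy'."""
        gx = np.linspace(-self.width_cm / 2, self.width_cm / 2, self.grid_resolution)
        gy = np.linspace(-self.height_cm / 2, self.height_cm / 2, self.grid_resolution)
        return np.meshgrid(gx, gy)


@dataclass(frozen=True)
class SceneSpec:
    """Dot-cloud or fronto-parallel-plane scene."""

    kind: str = "cloud"  # {"cloud", "plane"}
    near_clip_cm: float = 25.0
    far_clip_cm: float = 125.0
    plane_distance_cm: float = 45.0
    dot_density: float = 0.002  # dots/cm^3 (cloud) or dots/cm^2 (plane)

    def __post_init__(self) -> None:
        if self.kind not in ("cloud", "plane"):
            raise ValueError("scene kind must be 'cloud' or 'plane'")
        if self.near_clip_cm >= self.far_clip_cm:
            raise ValueError("near clip must be closer than far clip")
        if self.dot_density <= 0:
            raise ValueError("dot density must be positive")


@dataclass
class VelocityField:
    """Screen velocity vectors sampled on a regular grid."""

    x_cm: np.ndarray
    y_cm: np.ndarray
    vx_cm_s: np.ndarray
    vy_cm_s: np.ndarray
    depth_cm: float
    degenerate: bool = False

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x_cm": self.x_cm.ravel(),
                "y_cm": self.y_cm.ravel(),
                "vx_cm_s": self.vx_cm_s.ravel(),
                "vy_cm_s": self.vy_cm_s.ravel(),
                "depth_cm": np.full(self.x_cm.size, self.depth_cm),
            }
        )


@dataclass(frozen=True)
class FOEResult:
    """Flow singularity on the horizontal meridian for one depth plane."""

    defined: bool
    azimuth_deg: float | None  # screen-linear degrees from straight ahead
    azimuth_atan_deg: float | None  # true visual angle, secondary
    x_cm: float | None
    depth_plane_cm: float


def screen_velocity(point, motion: SelfMotionState, screen: ScreenGeometry):
    """Screen velocity (vx, vy) cm/s of the projection of one scene point.

    ``point`` is (X, Y, Z) in eye coordinates, cm; Z must be positive
    (in front of the eye). Vectorized: X, Y, Z may be arrays.
    """
    X, Y, Z = (np.asarray(c, dtype=float) for c in point)
    if np.any(Z <= 0):
        raise ValueError("point behind eye")
    D = screen.viewing_distance_cm
    Tx, Ty, Tz = motion.translation_vector
    w = motion.yaw_rate_rad_s
    return velocity_at_screen(D * X / Z, D * Y / Z, Z, motion, screen)


def velocity_at_screen(x, y, Z, motion: SelfMotionState, screen: ScreenGeometry):
    """Screen velocity at screen position (x, y) cm of a point at depth Z.

    Differentiating x = D·X/Z, y = D·Y/Z with point motion −T − ω×P
    (ω about +y) and grouping terms: the rotational part depends only on
    the screen position, never on Z — the depth-invariance of rotational
    flow holds exactly here, to the last bit.
    """
    x, y, Z = (np.asarray(c, dtype=float) for c in (x, y, Z))
    if np.any(Z <= 0):
        raise ValueError("point behind eye")
    D = screen.viewing_distance_cm
    Tx, Ty, Tz = motion.translation_vector
    w = motion.yaw_rate_rad_s
    vx = (-D * Tx + x * Tz) / Z - w * (D + x**2 / D)
    vy = (-D * Ty + y * Tz) / Z - w * (x * y / D)
    return vx, vy


def flow_field(
    scene: SceneSpec,
    motion: SelfMotionState,
    screen: ScreenGeometry,
    depth_cm: float | None = None,
) -> VelocityField:
    """Velocity field on the screen grid for one depth slice of the scene.

    For a plane scene the slice is the plane distance; for a cloud a
    ``depth_cm`` within the clip range must be chosen (default: near clip).
    """
    if screen.grid_resolution < 1:
        raise ValueError("empty grid")
    if scene.kind == "plane":
        Z = scene.plane_distance_cm if depth_cm is None else depth_cm
    else:
        Z = scene.near_clip_cm if depth_cm is None else depth_cm
        if not (scene.near_clip_cm <= Z <= scene.far_clip_cm):
            raise ValueError("depth slice outside cloud clip range")
    gx, gy = screen.grid()
    vx, vy = velocity_at_screen(gx, gy, np.full_like(gx, Z), motion, screen)
    return VelocityField(gx, gy, vx, vy, depth_cm=Z)


def find_foe(
    motion: SelfMotionState, depth_plane_cm: float, screen: ScreenGeometry = ScreenGeometry()
) -> FOEResult:
    """Flow singularity along the horizontal meridian of a depth plane.

    Horizontal screen velocity on the meridian is quadratic in screen x:
    (ω/D)·x² − (Tz/Z)·x + D·(Tx/Z + ω) = 0. With two real roots the one
    continuously connected to the pure-translation FOE (x = D·Tx/Tz) is
    returned; a negative discriminant (rotation-dominated flow) means the
    FOE is undefined.
    """
    Z = float(depth_plane_cm)
    if Z <= 0:
        raise ValueError("depth plane must be in front of the eye")
    D = screen.viewing_distance_cm
    Tx, _, Tz = motion.translation_vector
    w = motion.yaw_rate_rad_s
    if abs(Tz) < 1e-12:
        # no forward/backward component: pure rotation or lateral slip
        return FOEResult(False, None, None, None, Z)
    x_trans = D * Tx / Tz  # FOE of the translation-only field
    if abs(w) < 1e-15:
        return _foe_from_x(x_trans, D, Z)
    a, b, c = w / D, -Tz / Z, D * (Tx / Z + w)
    disc = b * b - 4 * a * c
    if disc < 0:
        return FOEResult(False, None, None, None, Z)
    r = math.sqrt(disc)
    roots = ((-b - r) / (2 * a), (-b + r) / (2 * a))
    x = min(roots, key=lambda root: abs(root - x_trans))
    return _foe_from_x(x, D, Z)


def _foe_from_x(x: float, D: float, Z: float) -> FOEResult:
    return FOEResult(
        defined=True,
        azimuth_deg=math.degrees(x / D),
        azimuth_atan_deg=math.degrees(math.atan(x / D)),
        x_cm=x,
        depth_plane_cm=Z,
    )


def critical_foe_depth_cm(motion: SelfMotionState) -> float:
    """Depth beyond which the FOE is undefined, for forward heading: T/(2ω)."""
    w = abs(motion.yaw_rate_rad_s)
    if w == 0:
        return math.inf
    return motion.translation_speed_cm_s / (2 * w)


def foe_shift_timecourse(
    protocol: ProtocolSpec = ProtocolSpec(),
    screen: ScreenGeometry = ScreenGeometry(),
    start_distance_cm: float = 45.0,
    rotation_dir: str = "right",
    heading_deg: float = 90.0,
) -> tuple[float | None, float]:
    """Mean |FOE shift| over the plateau of an approach-a-wall trial.

    Evaluates ``find_foe`` at each display frame of the middle 750 ms with
    the plane distance following the approach schedule, and returns
    (time-average of defined shifts in degrees, fraction of frames with an
    undefined FOE). The average is None if the FOE is never defined.
    """
    t = protocol.time_grid_ms()
    lo, hi = protocol.plateau_window_ms
    t = t[(t >= lo) & (t <= hi)]
    sign = 1.0 if rotation_dir == "right" else -1.0
    shifts = []
    n_undef = 0
    for ti in t:
        motion = SelfMotionState(
            translation_speed_cm_s=trapezoid(ti, protocol.translation_peak_cm_s, protocol),
            heading_azimuth_deg=heading_deg,
            yaw_rate_deg_s=sign * trapezoid(ti, protocol.rotation_peak_deg_s, protocol),
        )
        Z = float(fp_distance_schedule(ti, protocol, start_distance_cm))
        res = find_foe(motion, Z, screen)
        if res.defined:
            shifts.append(abs(res.azimuth_deg))
        else:
            n_undef += 1
    frac_undef = n_undef / len(t)
    mean_shift = float(np.mean(shifts)) if shifts else None
    return mean_shift, frac_undef


def parallax_field(
    motion: SelfMotionState,
    z_near_cm: float,
    z_far_cm: float,
    screen: ScreenGeometry = ScreenGeometry(),
) -> VelocityField:
    """Motion-parallax field: near-slice flow minus far-slice flow.

    The rotational component is depth-independent and cancels exactly; the
    residual is (1/Z_near − 1/Z_far) times the unit-depth translational
    field, so its singularity sits at the true heading for any yaw rate.
    """
    if z_near_cm > z_far_cm:
        raise ValueError("Z_near must not exceed Z_far")
    scene = SceneSpec(kind="cloud", near_clip_cm=min(z_near_cm, 25.0), far_clip_cm=max(z_far_cm, 125.0))
    near = flow_field(scene, motion, screen, depth_cm=z_near_cm)
    far = flow_field(scene, motion, screen, depth_cm=z_far_cm)
    out = VelocityField(
        near.x_cm,
        near.y_cm,
        near.vx_cm_s - far.vx_cm_s,
        near.vy_cm_s - far.vy_cm_s,
        depth_cm=z_near_cm,
        degenerate=(z_near_cm == z_far_cm),
    )
    return out


def dynamic_perspective_residual(
    field: VelocityField, screen: ScreenGeometry = ScreenGeometry()
) -> VelocityField:
    """Rotation-only flow minus its central (foveal) laminar vector.

    The remainder is the dynamic-perspective component: zero at the screen
    center and growing with eccentricity. The input must come from a pure
    rotation (no translation), for which flow is depth-invariant.
    """
    # infer the yaw rate from the central vector, then require the whole
    # field to match the analytic rotation-only pattern
    # vx = -D*w - w*x^2/D, vy = -w*x*y/D (depth-independent)
    vx, vy = field.vx_cm_s, field.vy_cm_s
    gx, gy = field.x_cm, field.y_cm
    c_vx = _center_value(gx, gy, vx)
    c_vy = _center_value(gx, gy, vy)
    D = screen.viewing_distance_cm
    w = -c_vx / D
    exp_vx = -D * w - w * gx**2 / D
    exp_vy = -w * gx * gy / D
    scale = max(1.0, np.abs(vx).max(), np.abs(vy).max())
    if (
        max(np.abs(vx - exp_vx).max(), np.abs(vy - exp_vy).max()) > 1e-6 * scale
        or abs(c_vy) > 1e-9 * scale
    ):
        raise ValueError("field is not rotation-only")
    return VelocityField(
        field.x_cm, field.y_cm, vx - c_vx, vy - c_vy, depth_cm=field.depth_cm
    )


def _center_value(gx: np.ndarray, gy: np.ndarray, v: np.ndarray) -> float:
    i = np.unravel_index(np.argmin(gx**2 + gy**2), gx.shape)
    if abs(gx[i]) > 1e-9 or abs(gy[i]) > 1e-9:
        raise ValueError("grid has no central sample; use odd resolution")
    return float(v[i])
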