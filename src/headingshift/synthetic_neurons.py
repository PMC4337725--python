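"""Generative models of heading-tuned neurons under translation and rotation.

Tuning curves are von Mises functions of heading azimuth θ (deg),

    VM(θ)       = A·exp(k·[cos(θ−φ) − 1])
    VM_width(θ) = A·exp(k·[cos(θ−φ+σ·sin(θ−φ)) − 1])
    VM_skew(θ)  = A·exp(k·[cos(θ−φ+γ·cos(θ−φ)) − 1])

with peak rate A, preferred heading φ, concentration k, a second shape
parameter σ that changes the half-height slope (and hence bandwidth)
symmetrically, and a skew parameter γ that displaces the peak and trough in
opposite directions (≈ ∓γ radians for small γ) while skewing the flanks —
the signature of an uncompensated rotation for fore/aft heading
preferences. σ = γ = 0 recovers the plain von Mises.

Adding yaw rotation to translation transforms the tuning of a neuron that
responds to the resultant flow instead of heading. Because rotation
displaces the apparent heading oppositely for forward (0–180°) and backward
(180–360°) headings, the transformed curve is modeled as a
heading-half-referenced warp of the base curve,

    r(θ) = base(θ − d·u(θ)),   u(θ) = tanh(β·sin θ)/tanh(β),

which displaces the forward half by +d and the backward half by −d with a
smooth transition at the 0°/180° boundaries. For fore/aft preferences this
skews the curve and moves its peak by ≈ d; for lateral preferences (φ
within 20° of 0° or 180°) the two flanks move apart or together, changing
the bandwidth by ≈ 2d with the direction depending on φ and the rotation
direction. The warp amplitude is calibrated per neuron so the observable
deformation equals (1 − c) times the nominal effect (20° peak shift or 40°
FWHH change for the cloud stimulus), where c is the neuron's rotation
compensation: c = 1 is fully rotation-invariant, c = 0 responds to the
resultant flow, c > 1 over-compensates (deformation flips direction).

Trial noise is Poisson on spike counts in the 750 ms plateau window;
nuisance gain (0.66–1.33) and response offset (0–40 spikes/s) are drawn per
rotation-added condition. Time-resolved responses are inhomogeneous Poisson
spike trains whose drive follows the tuning curve evaluated at the heading
in eye coordinates, which drifts with the integrated rotation scaled by the
reference-frame weight λ (1 = eye-centered, 0 = head-centered).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .protocol import (
    PLATEAU_END_MS,
    PLATEAU_START_MS,
    ProtocolSpec,
    rotation_angle_deg,
)

PLATEAU_S = (PLATEAU_END_MS - PLATEAU_START_MS) / 1000.0

#: Lateral-preference bands (deg): [340, 20] around 0° and [160, 200] around 180°.
LATERAL_HALF_WIDTH_DEG = 20.0

#: Nominal half-displacement for an uncompensated (c = 0) neuron: the
#:  apparent-heading displacement of the near plane for the 3D cloud and the
#: plateau-average for the approaching fronto-parallel plane. The FWHH
#: change for lateral preferences is twice this (20° per half-curve).
NOMINAL_SHIFT_DEG = {"cloud": 20.0, "fp_plane": 37.0}

#: Sharpness of the forward/backward transition of the half-shift warp.
HALF_SHIFT_SHARPNESS = 4.0

DEFAULT_GAIN_RANGE = (0.66, 1.33)
DEFAULT_OFFSET_RANGE = (0.0, 40.0)


@dataclass(frozen=True)
class VonMisesParams:
    """Parameters of the (deformable) von Mises tuning curve."""

    A: float = 60.0  # peak rate, spikes/s
    phi_deg: float = 90.0  # preferred heading
    k: float = 3.0  # concentration (FWHH ≈ 81°)
    sigma: float = 0.0  # bandwidth/shape deformation
    gamma: float = 0.0  # skew deformation

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("peak rate A must be positive")
        if self.k <= 0:
            raise ValueError("concentration k must be positive")
        if not (np.isfinite(self.sigma) and np.isfinite(self.gamma)):
            raise ValueError("shape parameters must be finite")


def vm(theta_deg, p: VonMisesParams):
    """Plain von Mises tuning curve (σ and γ ignored)."""
    d = np.radians(np.asarray(theta_deg, dtype=float) - p.phi_deg)
    return p.A * np.exp(p.k * (np.cos(d) - 1.0))


def vm_width(theta_deg, p: VonMisesParams):
    """Von Mises with the bandwidth/shape deformation σ."""
    d = np.radians(np.asarray(theta_deg, dtype=float) - p.phi_deg)
    return p.A * np.exp(p.k * (np.cos(d + p.sigma * np.sin(d)) - 1.0))


def vm_skew(theta_deg, p: VonMisesParams):
    """Von Mises with the skew deformation γ (peak moves ≈ −γ radians)."""
    d = np.radians(np.asarray(theta_deg, dtype=float) - p.phi_deg)
    return p.A * np.exp(p.k * (np.cos(d + p.gamma * np.cos(d)) - 1.0))


@dataclass(frozen=True)
class WarpedVonMises:
    """Von Mises warped by the opposite-half displacement of rotation.

    ``half_shift_deg`` is the displacement of the forward (0–180°) heading
    half; the backward half moves by the same amount in the opposite
    direction, with a smooth tanh transition at the boundaries.
    """

    base: VonMisesParams
    half_shift_deg: float
    sharpness: float = HALF_SHIFT_SHARPNESS

    @property
    def A(self) -> float:
        return self.base.A

    @property
    def phi_deg(self) -> float:
        return self.base.phi_deg


def half_shift_profile(theta_deg, sharpness: float = HALF_SHIFT_SHARPNESS):
    """Smoothed ±1 profile over the circle: +1 forward, −1 backward."""
    s = np.sin(np.radians(np.asarray(theta_deg, dtype=float)))
    return np.tanh(sharpness * s) / np.tanh(sharpness)


CurveModel = "VonMisesParams | WarpedVonMises"


def evaluate(theta_deg, p):
    """Tuning curve with whatever deformations the model carries."""
    if isinstance(p, WarpedVonMises):
        th = np.asarray(theta_deg, dtype=float)
        warped = th - p.half_shift_deg * half_shift_profile(th, p.sharpness)
        return evaluate(warped, p.base)
    d = np.radians(np.asarray(theta_deg, dtype=float) - p.phi_deg)
    arg = d + p.sigma * np.sin(d) + p.gamma * np.cos(d)
    return p.A * np.exp(p.k * (np.cos(arg) - 1.0))


def vm_fwhh_deg(k: float) -> float:
    """Width at half the PEAK amplitude: 2·acos(1 − ln2/k) (k ≥ ln2).

    Note the measured-curve FWHH (:func:`population_metrics.fwhh`) uses the
    (min + max)/2 crossing, which is slightly narrower because the von
    Mises trough is nonzero.
    """
    c = 1.0 - np.log(2.0) / k
    if c < -1.0:
        return 360.0  # never falls to half height
    return float(2.0 * np.degrees(np.arccos(c)))


_FINE_GRID = np.arange(0.0, 360.0, 0.01)


def peak_heading_deg(p) -> float:
    """Numeric location of the tuning peak on a 0.01° grid."""
    return float(_FINE_GRID[np.argmax(evaluate(_FINE_GRID, p))])


def numeric_fwhh_deg(p) -> float:
    """Numeric FWHH of the (possibly deformed) curve."""
    from .population_metrics import fwhh

    return fwhh(evaluate(_FINE_GRID, p), step_deg=0.01)


def _circ_diff(a: float, b: float) -> float:
    return (a - b + 180.0) % 360.0 - 180.0


def is_lateral_preference(phi_deg: float) -> bool:
    """True if φ lies strictly inside the lateral bands (340°:20°), (160°:200°).

    Preferences exactly 20° from lateral sit on the band edge, where the
    bandwidth-change and peak-shift descriptions of the rotation effect
    coincide in magnitude; they are treated as fore/aft.
    """
    d0 = abs(_circ_diff(phi_deg, 0.0))
    d180 = abs(_circ_diff(phi_deg, 180.0))
    return min(d0, d180) < LATERAL_HALF_WIDTH_DEG


def calibrate_gamma(base: VonMisesParams, target_shift_deg: float) -> float:
    """Skew γ that displaces the numeric peak by ``target_shift_deg``."""
    if target_shift_deg == 0.0:
        return 0.0

    def disp(g: float) -> float:
        return _circ_diff(
            peak_heading_deg(replace(base, gamma=g, sigma=0.0)), base.phi_deg
        ) - target_shift_deg

    # peak displacement ≈ -gamma radians: positive targets need gamma < 0
    lo, hi = (-2.0, 0.0) if target_shift_deg > 0 else (0.0, 2.0)
    return float(optimize.brentq(disp, lo, hi, xtol=1e-6))


def calibrate_sigma(base: VonMisesParams, target_fwhh_change_deg: float) -> float:
    """Shape σ that changes the numeric FWHH by ``target_fwhh_change_deg``."""
    if target_fwhh_change_deg == 0.0:
        return 0.0
    w0 = numeric_fwhh_deg(replace(base, sigma=0.0, gamma=0.0))
    target = w0 + target_fwhh_change_deg

    def err(s: float) -> float:
        return numeric_fwhh_deg(replace(base, sigma=s, gamma=0.0)) - target

    # sigma > 0 narrows, sigma < 0 widens; stay above the fold at sigma = -1
    lo, hi = (-0.99, 0.0) if target_fwhh_change_deg > 0 else (0.0, 2.5)
    return float(optimize.brentq(err, lo, hi, xtol=1e-6))


def expected_peak_shift_sign(phi_deg: float, rotation_dir: str) -> int:
    """Geometric direction of the tuning-peak displacement for c = 0.

    Rightward rotation displaces forward-preferring peaks toward larger
    azimuths (+1) and backward-preferring peaks toward smaller azimuths
    (−1); leftward rotation mirrors both. Undefined for lateral φ.
    """
    forward = np.sin(np.radians(phi_deg)) > 0
    s = 1 if forward else -1
    return s if rotation_dir == "right" else -s


def expected_bandwidth_sign(phi_deg: float, rotation_dir: str) -> int:
    """+1 if rotation widens a lateral-preferring curve, −1 if it narrows.

    Rightward rotation widens 0°-preferring and narrows 180°-preferring
    tuning; leftward rotation mirrors both.
    """
    near_zero = abs(_circ_diff(phi_deg, 0.0)) <= LATERAL_HALF_WIDTH_DEG
    s = 1 if near_zero else -1
    return s if rotation_dir == "right" else -s


def calibrate_half_shift(
    base: VonMisesParams, rotation_dir: str, target_deg: float
) -> float:
    """Warp amplitude hitting the observable deformation exactly.

    ``target_deg`` is the signed nominal half-displacement (positive =
    under-compensation for the given rotation direction; the forward half
    moves +target for rightward rotation, −target for leftward). For
    fore/aft preferences the amplitude is tuned so the numeric peak
    displacement equals the geometric expectation; for lateral preferences
    so the FWHH change equals twice the target.
    """
    if target_deg == 0.0:
        return 0.0
    s_rot = 1.0 if rotation_dir == "right" else -1.0
    d_nominal = s_rot * target_deg

    if is_lateral_preference(base.phi_deg):
        want = 2.0 * target_deg * expected_bandwidth_sign(base.phi_deg, rotation_dir)
        w0 = numeric_fwhh_deg(base)

        def err(d: float) -> float:
            return numeric_fwhh_deg(WarpedVonMises(base, d)) - (w0 + want)

    else:
        want = target_deg * expected_peak_shift_sign(base.phi_deg, rotation_dir)

        def err(d: float) -> float:
            return _circ_diff(peak_heading_deg(WarpedVonMises(base, d)), base.phi_deg) - want

    lo, hi = sorted((0.5 * d_nominal, 1.6 * d_nominal))
    if err(lo) * err(hi) > 0:  # fall back to the nominal amplitude
        return d_nominal
    return float(optimize.brentq(err, lo, hi, xtol=1e-4))


def make_rotation_added_curve(
    base: VonMisesParams,
    rotation_dir: str,
    stimulus: str = "cloud",
    c: float = 0.0,
    mode: str = "peak_shift",
):
    """Tuning-curve model of the rotation-added condition for compensation c.

    The deformation magnitude is (1 − c) times the nominal effect of the
    stimulus; c = 1 returns the base parameters unchanged (rotation
    invariance), c > 1 flips the deformation direction (over-compensation).

    ``mode="peak_shift"`` (default, the construction used to validate the
    estimator): fore/aft-preferring neurons get a rigid displacement of the
    preferred direction by the geometrically expected (1 − c)·20° (cloud),
    lateral-preferring neurons a σ bandwidth deformation of (1 − c)·40°
    FWHH with the direction rules of the geometry.

    ``mode="geometric"`` applies the opposite-half warp
    (:class:`WarpedVonMises`) instead, displacing forward and backward
    heading halves in opposite directions as rotation actually does.
    """
    if c < 0:
        raise ValueError("compensation must be non-negative")
    if rotation_dir not in ("left", "right"):
        raise ValueError(f"unknown rotation direction {rotation_dir!r}")
    residual = 1.0 - c
    if residual == 0.0:
        return replace(base, sigma=0.0, gamma=0.0)
    target = residual * NOMINAL_SHIFT_DEG[stimulus]
    if mode == "geometric":
        return WarpedVonMises(base, calibrate_half_shift(base, rotation_dir, target))
    if mode != "peak_shift":
        raise ValueError(f"unknown mode {mode!r}")
    if is_lateral_preference(base.phi_deg):
        change = 2.0 * target * expected_bandwidth_sign(base.phi_deg, rotation_dir)
        return replace(base, sigma=calibrate_sigma(base, change), gamma=0.0)
    shift = target * expected_peak_shift_sign(base.phi_deg, rotation_dir)
    return replace(base, phi_deg=(base.phi_deg + shift) % 360.0, sigma=0.0, gamma=0.0)


@dataclass(frozen=True)
class NeuronSpec:
    """Full generative description of one synthetic neuron."""

    base: VonMisesParams = VonMisesParams()
    c_rp: float = 1.0  # compensation during real pursuit
    c_sp: float = 1.0  # compensation during simulated pursuit
    frame_weight: float = 1.0  # λ: 1 eye-centered, 0 head-centered
    baseline_sps: float = 5.0
    spontaneous_sps: float | None = None  # blank-screen rate; default baseline
    rot_nonvisual_sps: tuple[float, float] = (0.0, 0.0)  # (left, right)
    rot_visual_sps: tuple[float, float] = (0.0, 0.0)  # (left, right)
    gain_range: tuple[float, float] = DEFAULT_GAIN_RANGE
    offset_range: tuple[float, float] = DEFAULT_OFFSET_RANGE
    deformation_mode: str = "peak_shift"  # or "geometric"

    def __post_init__(self) -> None:
        if self.baseline_sps < 0:
            raise ValueError("baseline must be non-negative")
        for c in (self.c_rp, self.c_sp):
            if not 0.0 <= c <= 1.2:
                raise ValueError("compensation must lie in [0, 1.2]")
        if not 0.0 <= self.frame_weight <= 1.0:
            raise ValueError("frame weight must lie in [0, 1]")

    def condition_curve(self, condition_type: str, rotation_dir: str | None,
                        stimulus: str = "cloud") -> VonMisesParams:
        """Static tuning parameters for one condition type."""
        if condition_type == "translation":
            return self.base
        c = self.c_rp if condition_type == "RP" else self.c_sp
        return make_rotation_added_curve(
            self.base, rotation_dir, stimulus, c, mode=self.deformation_mode
        )

    def rotation_response(self, label: str, rotation_dir: str) -> float:
        """Extra firing (sp/s) driven by the rotation itself."""
        i = 0 if rotation_dir == "left" else 1
        nonvis, vis = self.rot_nonvisual_sps[i], self.rot_visual_sps[i]
        return {
            "RP": nonvis + vis,
            "SP": vis,
            "pursuit_dark": nonvis,
            "pursuit_static": nonvis,
            "sim_rotation": vis,
        }.get(label, 0.0)


def _poisson_rates(rng: np.random.Generator, expected_sps, reps: int) -> np.ndarray:
    """Trial rates: Poisson counts over the plateau window, back to sp/s."""
    lam = np.asarray(expected_sps, dtype=float) * PLATEAU_S
    if np.any(lam < 0):
        warnings.warn("negative expected rate clipped at 0", stacklevel=3)
        lam = np.clip(lam, 0.0, None)
    counts = rng.poisson(lam[None, :].repeat(reps, axis=0))
    return counts / PLATEAU_S


def simulate_trials(
    neuron: NeuronSpec,
    protocol: ProtocolSpec = ProtocolSpec(),
    reps: int = 5,
    seed: int | None = None,
    neuron_id: object = 0,
    stimulus: str = "cloud",
    include_controls: bool = False,
    noise: bool = True,
) -> pd.DataFrame:
    """Trial table (neuron_id, condition, heading_deg, repetition, rate_sps).

    Per rotation-added condition a gain and an offset are drawn once and
    applied to the tuning curve; rotation-driven response components are
    added where the condition contains rotation; Poisson noise converts
    expected rates to trial rates (``noise=False`` yields the noiseless
    expectations, for oracle tests).
    """
    if reps < 1:
        raise ValueError("need at least one repetition")
    rng = np.random.default_rng(seed)
    headings = np.asarray(protocol.headings_deg, dtype=float)
    rows: list[pd.DataFrame] = []

    def emit(condition: str, heading_deg, expected_sps) -> None:
        expected = np.atleast_1d(np.asarray(expected_sps, dtype=float))
        hs = np.atleast_1d(np.asarray(heading_deg, dtype=float))
        rates = (
            _poisson_rates(rng, expected, reps)
            if noise
            else np.clip(expected, 0, None)[None, :].repeat(reps, axis=0)
        )
        rep_idx, h_idx = np.meshgrid(np.arange(reps), np.arange(hs.size), indexing="ij")
        rows.append(
            pd.DataFrame(
                {
                    "neuron_id": neuron_id,
                    "condition": condition,
                    "heading_deg": hs[h_idx.ravel()],
                    "repetition": rep_idx.ravel(),
                    "rate_sps": rates.ravel(),
                }
            )
        )

    emit("translation_only", headings, neuron.baseline_sps + vm(headings, neuron.base))
    for ct in ("RP", "SP"):
        for direction in ("left", "right"):
            curve = neuron.condition_curve(ct, direction, stimulus)
            gain = rng.uniform(*neuron.gain_range)
            offset = rng.uniform(*neuron.offset_range)
            expected = (
                gain * evaluate(headings, curve)
                + offset
                + neuron.baseline_sps
                + neuron.rotation_response(ct, direction)
            )
            emit(f"{ct}_{direction}", headings, expected)
    if include_controls:
        spont = (
            neuron.spontaneous_sps
            if neuron.spontaneous_sps is not None
            else neuron.baseline_sps
        )
        for label in ("pursuit_dark", "pursuit_static", "sim_rotation"):
            for direction in ("left", "right"):
                expected = neuron.baseline_sps + neuron.rotation_response(
                    label, direction
                )
                emit(f"{label}_{direction}", np.nan, expected)
        emit("blank", np.nan, spont)
        emit("static_fix", np.nan, neuron.baseline_sps)
    return pd.concat(rows, ignore_index=True)


def simulate_validation_suite(
    n_sets: int = 10,
    seed: int | None = None,
    preferences_deg: np.ndarray | None = None,
    k: float = 3.0,
    A: float = 60.0,
    reps: int = 5,
    baseline_sps: float = 0.0,
    noise: bool = True,
    gain_range: tuple[float, float] = DEFAULT_GAIN_RANGE,
    offset_range: tuple[float, float] = DEFAULT_OFFSET_RANGE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The estimator-validation simulation: known 20° transformations.

    ``n_sets`` replicate sets of neurons with preferred headings spanning
    0–360° (default: every 20°). Each neuron is fully uncompensated
    (c = 0): lateral preferences receive the 40° bandwidth deformation,
    all others the 20° peak-shift skew. Rotation-added (SP) curves get a
    random gain in ``gain_range`` and offset in ``offset_range``, all
    curves get Poisson noise over ``reps`` repetitions, sampled at 45°.

    Returns (trial table, ground-truth table with the 20° true shift).
    """
    if preferences_deg is None:
        preferences_deg = np.arange(0.0, 360.0, 20.0)
    ss = np.random.SeedSequence(seed)
    child = iter(ss.spawn(n_sets * len(preferences_deg)))
    frames, truth = [], []
    for s in range(n_sets):
        for phi in preferences_deg:
            nid = f"set{s:02d}_pref{int(round(phi)) % 360:03d}"
            neuron = NeuronSpec(
                base=VonMisesParams(A=A, phi_deg=float(phi), k=k),
                c_rp=0.0,
                c_sp=0.0,
                baseline_sps=baseline_sps,
                gain_range=gain_range,
                offset_range=offset_range,
            )
            df = simulate_trials(
                neuron,
                reps=reps,
                seed=next(child).generate_state(1)[0] % (2**31),
                neuron_id=nid,
                noise=noise,
            )
            df = df[df["condition"].isin(["translation_only", "SP_left", "SP_right"])]
            frames.append(df)
            truth.append(
                {
                    "neuron_id": nid,
                    "set": s,
                    "preference_deg": float(phi),
                    "true_shift_deg": 20.0,
                    "deformation": "sigma" if is_lateral_preference(phi) else "gamma",
                }
            )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truth)


def sample_population(
    n: int = 72,
    seed: int | None = None,
    preference_range_deg: tuple[float, float] = (0.0, 360.0),
    amplitude_range_sps: tuple[float, float] = (30.0, 80.0),
    k: float = 3.0,
    c_rp_range: tuple[float, float] = (1.0, 1.0),
    c_sp_range: tuple[float, float] = (1.0, 1.0),
    frame_weight: float = 1.0,
    baseline_sps: float = 5.0,
    rotation_amp_sps: float = 0.0,
    deformation_mode: str = "peak_shift",
) -> list[NeuronSpec]:
    """Random population of synthetic neurons for population-level studies.

    Preferences and peak amplitudes are uniform over the given ranges;
    per-condition compensation values c are uniform over theirs; rotation
    sensitivities (visual and non-visual, per direction) are zero-mean
    normal with SD ``rotation_amp_sps``.
    """
    rng = np.random.default_rng(seed)
    pop = []
    for _ in range(n):
        pop.append(
            NeuronSpec(
                base=VonMisesParams(
                    A=float(rng.uniform(*amplitude_range_sps)),
                    phi_deg=float(rng.uniform(*preference_range_deg)) % 360.0,
                    k=k,
                ),
                c_rp=float(rng.uniform(*c_rp_range)),
                c_sp=float(rng.uniform(*c_sp_range)),
                frame_weight=frame_weight,
                baseline_sps=baseline_sps,
                rot_nonvisual_sps=tuple(rng.normal(0, rotation_amp_sps, 2)),
                rot_visual_sps=tuple(rng.normal(0, rotation_amp_sps, 2)),
                deformation_mode=deformation_mode,
            )
        )
    return pop


def eye_heading_deg(
    heading_deg: float,
    rotation_dir: str | None,
    t_ms: np.ndarray,
    frame_weight: float,
    protocol: ProtocolSpec = ProtocolSpec(),
) -> np.ndarray:
    """Heading in eye coordinates over the trial.

    With λ = ``frame_weight``, the eye-coordinate heading drifts with the
    integrated rotation (centered on mid-trial so the sweep is symmetric):
    λ = 1 gives the full eye-centered drift, λ = 0 a constant heading.
    """
    t = np.asarray(t_ms, dtype=float)
    if rotation_dir is None:
        return np.full_like(t, heading_deg)
    angle = rotation_angle_deg(rotation_dir, t, protocol)
    mid = rotation_angle_deg(rotation_dir, protocol.trial_duration_ms / 2, protocol)
    return heading_deg + frame_weight * (angle - mid)


def temporal_rate(
    neuron: NeuronSpec,
    condition_type: str,
    rotation_dir: str | None,
    heading_deg: float,
    t_ms: np.ndarray,
    protocol: ProtocolSpec = ProtocolSpec(),
    stimulus: str = "cloud",
) -> np.ndarray:
    """Noise-free instantaneous drive (sp/s) over the trial at one heading."""
    curve = neuron.condition_curve(
        "translation" if condition_type == "translation" else condition_type,
        rotation_dir,
        stimulus,
    )
    h_eye = eye_heading_deg(
        heading_deg, rotation_dir, t_ms, neuron.frame_weight, protocol
    )
    rate = neuron.baseline_sps + evaluate(h_eye, curve)
    if rotation_dir is not None and condition_type in ("RP", "SP"):
        rate = rate + neuron.rotation_response(condition_type, rotation_dir)
    return rate


def simulate_spike_train(
    rate_sps: np.ndarray,
    rng: np.random.Generator,
    dt_ms: float = 1.0,
) -> np.ndarray:
    """Inhomogeneous Poisson spike times (ms) for a rate on a uniform grid."""
    lam = np.clip(np.asarray(rate_sps, dtype=float), 0, None) * dt_ms / 1000.0
    counts = rng.poisson(lam)
    idx = np.repeat(np.arange(lam.size), counts)
    return (idx + rng.uniform(size=idx.size)) * dt_ms


def simulate_temporal_response(
    neuron: NeuronSpec,
    condition_type: str,
    rotation_dir: str | None,
    heading_deg: float,
    protocol: ProtocolSpec = ProtocolSpec(),
    seed: int | None = None,
    reps: int = 5,
    dt_ms: float = 1.0,
) -> list[np.ndarray]:
    """Spike-event times (ms) for ``reps`` trials of one condition/heading."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, protocol.trial_duration_ms, dt_ms)
    rate = temporal_rate(neuron, condition_type, rotation_dir, heading_deg, t, protocol)
    return [simulate_spike_train(rate, rng, dt_ms) for _ in range(reps)]


def simulate_temporal_dataset(
    population: list[NeuronSpec],
    protocol: ProtocolSpec = ProtocolSpec(),
    reps: int = 5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rates plus spike events for the five main conditions, all headings.

    Returns (trials, spikes): the trial table as in :func:`simulate_trials`
    (rates taken from the plateau window of the spike trains, so the two
    tables are consistent) and a spike table (neuron_id, condition,
    heading_deg, repetition, t_ms).
    """
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(population)))
    t = np.arange(0.0, protocol.trial_duration_ms, 1.0)
    in_win = (t >= PLATEAU_START_MS) & (t < PLATEAU_END_MS)
    conds = [("translation", None)] + [
        (ct, d) for ct in ("RP", "SP") for d in ("left", "right")
    ]
    trial_rows, spike_rows = [], []
    for nid, neuron in enumerate(population):
        rng = np.random.default_rng(next(children).generate_state(1)[0] % (2**31))
        for ct, d in conds:
            label = "translation_only" if ct == "translation" else f"{ct}_{d}"
            for h in protocol.headings_deg:
                rate = temporal_rate(neuron, ct, d, h, t, protocol)
                lam = np.clip(rate, 0, None) / 1000.0
                counts = rng.poisson(lam[None, :].repeat(reps, axis=0))
                for r in range(reps):
                    c = counts[r]
                    n_spk = int(c.sum())
                    if n_spk:
                        idx = np.repeat(np.arange(t.size), c)
                        times = idx + rng.uniform(size=n_spk)
                        spike_rows.append(
                            pd.DataFrame(
                                {
                                    "neuron_id": nid,
                                    "condition": label,
                                    "heading_deg": h,
                                    "repetition": r,
                                    "t_ms": times,
                                }
                            )
                        )
                    trial_rows.append(
                        {
                            "neuron_id": nid,
                            "condition": label,
                            "heading_deg": h,
                            "repetition": r,
                            "rate_sps": c[in_win].sum() / PLATEAU_S,
                        }
                    )
    trials = pd.DataFrame(trial_rows)
    spikes = (
        pd.concat(spike_rows, ignore_index=True)
        if spike_rows
        else pd.DataFrame(
            columns=["neuron_id", "condition", "heading_deg", "repetition", "t_ms"]
        )
    )
    return trials, spikes


def simulate_rotation_responses(
    population: list[NeuronSpec],
    rho: float,
    seed: int | None = None,
    reps: int = 5,
    amplitude_sps: float = 15.0,
) -> pd.DataFrame:
    """Paired pursuit-in-darkness / simulated-rotation control responses.

    Per neuron and rotation direction, latent response amplitudes for the
    non-visual (pursuit in darkness) and visual (simulated rotation)
    rotation drives are drawn from a bivariate normal with correlation
    ``rho``; trials add Poisson noise on top of the neuron's baseline.
    Includes baseline (blank) trials. Returns a trial table restricted to
    the control conditions.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|rho| must not exceed 1")
    rng = np.random.default_rng(seed)
    cov = amplitude_sps**2 * np.array([[1.0, rho], [rho, 1.0]])
    frames = []
    for nid, neuron in enumerate(population):
        spec_rows = {}
        for direction in ("left", "right"):
            nonvis, vis = rng.multivariate_normal([0.0, 0.0], cov)
            spec_rows[f"pursuit_dark_{direction}"] = neuron.baseline_sps + nonvis
            spec_rows[f"sim_rotation_{direction}"] = neuron.baseline_sps + vis
        spec_rows["blank"] = neuron.baseline_sps
        for cond, expected in spec_rows.items():
            rates = _poisson_rates(rng, np.array([expected]), reps).ravel()
            frames.append(
                pd.DataFrame(
                    {
                        "neuron_id": nid,
                        "condition": cond,
                        "heading_deg": np.nan,
                        "repetition": np.arange(reps),
                        "rate_sps": rates,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
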