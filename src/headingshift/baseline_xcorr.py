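"""Legacy cross-correlation shift estimator over a narrow heading range.

Earlier studies measured heading tuning only within ±32° of straight ahead
(8° sampling, 9 points), smoothed with a three-point moving average,
spline-interpolated to 1°, and estimated the tuning shift as the lag
maximizing the correlation coefficient between the translation-only and
rotation-added curves. Because the correlation coefficient is invariant to
gain and offset, the method works when a symmetric tuning peak lies inside
the window (preferences near straight ahead) but returns unreliable, flat
correlation functions for lateral heading preferences whose curves are
monotonic inside the window — the failure this module demonstrates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .synthetic_neurons import (
    DEFAULT_GAIN_RANGE,
    DEFAULT_OFFSET_RANGE,
    VonMisesParams,
    evaluate,
    make_rotation_added_curve,
    vm,
)

STRAIGHT_AHEAD_DEG = 90.0

#: Headings sampled relative to straight ahead: ±32° in 8° steps.
NARROW_OFFSETS_DEG = np.arange(-32.0, 33.0, 8.0)

DEFAULT_LAG_WINDOW_DEG = 30
MIN_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class XcorrResult:
    lag_deg: int
    peak_r: float


def smooth3(values: np.ndarray) -> np.ndarray:
    """Three-point moving average; two-point at the (non-circular) ends."""
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    out[0] = v[:2].mean()
    out[-1] = v[-2:].mean()
    out[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    return out


def spline_to_1deg(offsets_deg: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Natural cubic spline of the smoothed samples on a 1° grid."""
    grid = np.arange(offsets_deg[0], offsets_deg[-1] + 1.0)
    return CubicSpline(offsets_deg, values, bc_type="natural")(grid)


def xcorr_shift(
    ref: np.ndarray,
    test: np.ndarray,
    offsets_deg: np.ndarray = NARROW_OFFSETS_DEG,
    lag_window_deg: int = DEFAULT_LAG_WINDOW_DEG,
) -> XcorrResult:
    """Max-correlation lag between two narrow tuning curves.

    ``ref`` and ``test`` are the 9 sampled rates. Both are smoothed and
    splined to 1°; the test curve is compared to the reference displaced by
    every integer lag in ±``lag_window_deg`` (positive lag = test curve
    displaced toward larger azimuths); lags leaving less than half the
    samples overlapping are excluded. Zero-variance curves are flagged by a
    ``ValueError``.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != offsets_deg.shape or test.shape != offsets_deg.shape:
        raise ValueError("curves must match the narrow sampling grid")
    rd = spline_to_1deg(offsets_deg, smooth3(ref))
    td = spline_to_1deg(offsets_deg, smooth3(test))
    n = rd.size
    min_overlap = int(np.ceil(MIN_OVERLAP_FRACTION * n))
    best: tuple[float, int, float] | None = None  # (-r, |lag|, lag)
    results = []
    for lag in range(-lag_window_deg, lag_window_deg + 1):
        # test(θ) compared with ref(θ - lag) on the overlapping support
        if lag >= 0:
            a, b = rd[: n - lag], td[lag:]
        else:
            a, b = rd[-lag:], td[: n + lag]
        if a.size < min_overlap:
            continue
        if np.std(a) == 0 or np.std(b) == 0:
            raise ValueError("zero-variance curve: correlation undefined")
        r = float(np.corrcoef(a, b)[0, 1])
        results.append((lag, r))
    if not results:
        raise ValueError("no admissible lags")
    lag, r = min(results, key=lambda t: (-t[1], abs(t[0]), t[0]))
    return XcorrResult(lag_deg=int(lag), peak_r=r)


def sample_narrow_curves(
    preference_deg: float,
    rng: np.random.Generator,
    k: float = 3.0,
    A: float = 60.0,
    reps: int = 5,
    true_shift_deg: float = 20.0,
    noise: bool = True,
    randomize_gain_offset: bool = True,
    gain_range: tuple[float, float] = DEFAULT_GAIN_RANGE,
    offset_range: tuple[float, float] = DEFAULT_OFFSET_RANGE,
) -> dict[str, np.ndarray]:
    """Translation and rotation-added curves sampled at ±32° around ahead.

    The rotation-added curves carry the same preference-band deformations
    as the wide-field simulations (peak displacement ``true_shift_deg`` for
    fore/aft preferences, bandwidth change for lateral), with optional
    per-curve gain/offset randomization and Poisson trial noise averaged
    over ``reps`` repetitions.
    """
    from .synthetic_neurons import PLATEAU_S

    base = VonMisesParams(A=A, phi_deg=preference_deg, k=k)
    headings = STRAIGHT_AHEAD_DEG + NARROW_OFFSETS_DEG
    out = {"translation_only": vm(headings, base)}
    c1 = 1.0 - true_shift_deg / 20.0  # compensation giving the requested shift
    for direction in ("left", "right"):
        curve = make_rotation_added_curve(base, direction, "cloud", c=c1)
        expected = evaluate(headings, curve)
        if randomize_gain_offset:
            expected = rng.uniform(*gain_range) * expected + rng.uniform(*offset_range)
        out[f"rotation_{direction}"] = expected
    if noise:
        for key, expected in out.items():
            lam = np.clip(expected, 0, None) * PLATEAU_S
            counts = rng.poisson(lam[None, :].repeat(reps, axis=0))
            out[key] = counts.mean(axis=0) / PLATEAU_S
    return out


def xcorr_benchmark(
    preferences_deg: np.ndarray | None = None,
    n_sets: int = 10,
    seed: int | None = None,
    **curve_kwargs,
) -> pd.DataFrame:
    """Bias/variance profile of the cross-correlation estimator.

    For each heading preference, ``n_sets`` independently noisy curve sets
    are generated and the estimator's lag is recorded for both rotation
    directions (leftward lags negated so the expected value is always the
    positive true shift). Returns per-preference mean, SD and mean peak
    correlation.
    """
    if preferences_deg is None:
        preferences_deg = np.linspace(0.0, 180.0, 10)
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(preferences_deg) * n_sets))
    rows = []
    for pref in preferences_deg:
        lags, peaks = [], []
        for _ in range(n_sets):
            rng = np.random.default_rng(next(children).generate_state(1)[0] % (2**31))
            curves = sample_narrow_curves(pref, rng, **curve_kwargs)
            for direction, sign in (("right", 1.0), ("left", -1.0)):
                res = xcorr_shift(curves["translation_only"], curves[f"rotation_{direction}"])
                lags.append(sign * res.lag_deg)
                peaks.append(res.peak_r)
        rows.append(
            {
                "preference_deg": float(pref),
                "mean_lag_deg": float(np.mean(lags)),
                "sd_lag_deg": float(np.std(lags, ddof=1)),
                "mean_peak_r": float(np.mean(peaks)),
                "n": len(lags),
            }
        )
    return pd.DataFrame(rows)
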