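"""Partial-shift estimation of heading-tuning transformations under rotation.

The estimator quantifies how much a rotation-added tuning curve (real or
simulated pursuit) is displaced relative to the pure-translation curve of
the same neuron, in three steps:

1. Normalization — the rotation-added curve is vertically shifted and
   scaled so its trough and dynamic range match the pure-translation curve.
2. Gating and interpolation — each half of the curve (forward headings
   0–180°, backward headings 180–360°; boundaries shared) is tested for
   significant tuning with a one-way ANOVA across headings (p ≤ 0.05), and
   both curves are linearly interpolated on the circle to 1° resolution.
3. Shift search — the pure-translation curve is circularly shifted in 1°
   steps to minimize the sum-squared error against each significantly tuned
   half; the minimizing lag is that half's partial shift.

Because rotation displaces forward- and backward-heading flow singularities
in opposite directions, the four partial shifts (two halves × two rotation
directions) are sign-aligned before averaging so that positive means
under-compensation for rotation. Percentile bootstrap confidence intervals
resample trials with replacement within each heading × condition cell and
rerun the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

HALVES = ("forward", "backward")

#: Per-half expected sign of the measured lag for an under-compensating
#: LATERAL-preferring neuron: rightward rotation widens 0°-preferring
#: tuning (forward flank moves to larger azimuths, backward flank to
#: smaller) and narrows 180°-preferring tuning (same per-half signs);
#: leftward rotation mirrors both. Multiplying the measured lag by the
#: table entry makes positive = under-compensation.
SIGN_TABLE: dict[tuple[str, str], int] = {
    ("forward", "right"): +1,
    ("forward", "left"): -1,
    ("backward", "right"): -1,
    ("backward", "left"): +1,
}

DENSE_STEP_DEG = 1.0
DEFAULT_SEARCH_WINDOW_DEG = 90


@dataclass
class ShiftResult:
    """Partial shifts and their sign-aligned mean for one neuron/condition."""

    neuron_id: object
    condition_type: str  # "RP" or "SP"
    partial_shifts: dict[tuple[str, str], float] = field(default_factory=dict)
    gate_pvalues: dict[tuple[str, str], float] = field(default_factory=dict)
    gated: dict[tuple[str, str], bool] = field(default_factory=dict)
    mean_shift: float | None = None
    ci95: tuple[float, float] | None = None
    n_boot: int = 0
    n_boot_dropped: int = 0

    @property
    def n_gated_halves(self) -> int:
        return sum(self.gated.values())


def normalize_to_reference(test_means: np.ndarray, ref_means: np.ndarray) -> np.ndarray:
    """Match trough and dynamic range of ``test_means`` to the reference.

    Affine map: output min equals min(ref) and output range equals
    range(ref) exactly, preserving the test curve's shape (rank order).
    A flat test curve cannot be normalized and raises ``ValueError``.
    """
    test = np.asarray(test_means, dtype=float)
    ref = np.asarray(ref_means, dtype=float)
    ref_range = ref.max() - ref.min()
    if ref_range <= 0:
        raise ValueError("reference curve has zero range")
    test_range = test.max() - test.min()
    if test_range <= 0:
        raise ValueError("test curve has zero range (untransformable)")
    return (test - test.min()) * (ref_range / test_range) + ref.min()


def half_headings(headings_deg: np.ndarray, half: str) -> np.ndarray:
    """Boolean mask of headings in one half; 0°/180°/360° sit in both."""
    h = np.asarray(headings_deg, dtype=float) % 360.0
    if half == "forward":
        return (h >= 0.0) & (h <= 180.0)
    if half == "backward":
        return (h >= 180.0) | (h == 0.0)
    raise ValueError(f"unknown half {half!r}")


def half_tuning_gate(
    headings_deg: np.ndarray,
    rates: np.ndarray,
    half: str,
    alpha: float = 0.05,
    interior_only: bool = True,
) -> tuple[float, bool]:
    """One-way ANOVA across the headings of one half of the tuning curve.

    ``headings_deg`` and ``rates`` are per-trial (flat, aligned). Returns
    (p-value, gated). Degenerate halves (fewer than two headings with two
    or more trials, or zero variance everywhere) are not gated.

    By default the ANOVA uses only the half's interior headings: the
    boundary headings 0°/180°/360° belong to both halves of the shift fit,
    so including them would let the tuned half's flank gate the untuned
    half — a half whose own interior carries no tuning would then pass the
    gate while the shift fit has no structure of that half's own to read.
    """
    h = np.asarray(headings_deg, dtype=float) % 360.0
    r = np.asarray(rates, dtype=float)
    mask = half_headings(h, half)
    if interior_only:
        mask &= (h != 0.0) & (h != 180.0)
    groups = [r[(h == hu) & mask] for hu in np.unique(h[mask])]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        return np.nan, False
    pooled = np.concatenate(groups)
    if np.allclose(pooled, pooled[0]):
        return 1.0, False
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.f_oneway(*groups)
    if np.isnan(p):
        return np.nan, False
    return float(p), bool(p <= alpha)


def interpolate_circular(
    headings_deg: np.ndarray, values: np.ndarray, step_deg: float = DENSE_STEP_DEG
) -> np.ndarray:
    """Piecewise-linear interpolation on the circle to a dense grid.

    Returns values on the grid 0, step, …, 360−step. The interpolant wraps
    (315° → 360°/0°) and passes through the sample points exactly.
    """
    h = np.asarray(headings_deg, dtype=float) % 360.0
    v = np.asarray(values, dtype=float)
    if len(np.unique(h)) != len(h):
        raise ValueError("duplicate headings")
    if len(h) < 3:
        raise ValueError("need at least 3 distinct headings")
    order = np.argsort(h)
    h, v = h[order], v[order]
    h_ext = np.concatenate([h, [h[0] + 360.0]])
    v_ext = np.concatenate([v, [v[0]]])
    grid = np.arange(0.0, 360.0, step_deg)
    # shift grid points below the first sample up by 360 so np.interp wraps
    g = np.where(grid < h[0], grid + 360.0, grid)
    return np.interp(g, h_ext, v_ext, period=360.0)


def _half_support(half: str, n: int = 360) -> np.ndarray:
    if half == "forward":
        return np.arange(0, 181)
    if half == "backward":
        return np.concatenate([np.arange(180, 360), [0]])
    raise ValueError(f"unknown half {half!r}")


def partial_shift(
    ref_dense: np.ndarray,
    test_dense: np.ndarray,
    half: str,
    window_deg: int = DEFAULT_SEARCH_WINDOW_DEG,
) -> int:
    """Lag (deg) of the circular shift of the reference minimizing SSE.

    The reference is rolled in 1° steps over ±``window_deg``; the SSE is
    evaluated only on the tested half's support (181 points). Positive lag
    means the test half looks like the reference displaced toward larger
    azimuths. Ties break toward the smaller |lag|.
    """
    ref = np.asarray(ref_dense, dtype=float)
    test = np.asarray(test_dense, dtype=float)
    if ref.shape != (360,) or test.shape != (360,):
        raise ValueError("dense curves must be sampled at 1° (360 points)")
    if np.ptp(ref) == 0:
        raise ValueError("shift undefined for a flat reference curve")
    support = _half_support(half)
    lags = np.arange(-window_deg, window_deg + 1)
    idx = (support[None, :] - lags[:, None]) % 360
    sse = ((ref[idx] - test[support][None, :]) ** 2).sum(axis=1)
    best = np.lexsort((lags, np.abs(lags), sse))[0]
    return int(lags[best])


def alignment_sign(
    half: str, rotation_dir: str, preference_deg: float | None
) -> int:
    """Sign making a partial shift positive under under-compensation.

    The expected displacement direction depends on the neuron's heading
    preference: a lateral-preferring neuron (within 20° of 0° or 180°)
    changes bandwidth, so its two halves move in opposite directions
    (per-half table); a fore/aft-preferring neuron's tuning is displaced as
    a whole in the direction of its preference's apparent-heading shift, so
    both halves share that sign. With an unknown preference the per-half
    table is used.
    """
    from .synthetic_neurons import expected_peak_shift_sign, is_lateral_preference

    if preference_deg is None or is_lateral_preference(preference_deg):
        return SIGN_TABLE[(half, rotation_dir)]
    return expected_peak_shift_sign(preference_deg, rotation_dir)


def mean_shift(
    partial_shifts: dict[tuple[str, str], float],
    mode: str = "signed",
    preference_deg: float | None = None,
) -> float:
    """Average the gated partial shifts into one per-condition shift.

    ``mode='signed'`` (default) sign-aligns each (half, rotation-direction)
    entry with :func:`alignment_sign` so positive = under-compensation;
    ``mode='absolute'`` averages absolute magnitudes instead.
    ``preference_deg`` is the neuron's preferred heading from its
    pure-translation curve (used by the signed alignment).
    """
    if not partial_shifts:
        raise ValueError("no gated partial shifts")
    if mode == "signed":
        vals = [
            alignment_sign(half, direction, preference_deg) * lag
            for (half, direction), lag in partial_shifts.items()
        ]
    elif mode == "absolute":
        vals = [abs(lag) for lag in partial_shifts.values()]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.mean(vals))


def _condition_means(df: pd.DataFrame, condition: str) -> tuple[np.ndarray, np.ndarray]:
    sub = df[df["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no trials for condition {condition!r}")
    g = sub.groupby("heading_deg")["rate_sps"].mean()
    return g.index.to_numpy(dtype=float), g.to_numpy(dtype=float)


def _shift_once(
    df: pd.DataFrame,
    condition_type: str,
    alpha: float,
    window_deg: int,
    mode: str,
    collect: ShiftResult | None = None,
    preference_deg: float | None = None,
) -> float | None:
    """Run the full 3-step pipeline on one neuron's trials; return mean shift."""
    ref_h, ref_means = _condition_means(df, "translation_only")
    if np.ptp(ref_means) == 0:
        return None
    ref_dense = interpolate_circular(ref_h, ref_means)
    if preference_deg is None:
        preference_deg = float(np.argmax(ref_dense))  # 1° grid
    shifts: dict[tuple[str, str], float] = {}
    for direction in ("left", "right"):
        cond = f"{condition_type}_{direction}"
        sub = df[df["condition"] == cond]
        if sub.empty:
            continue
        test_h, test_means = _condition_means(df, cond)
        if np.ptp(test_means) == 0:
            continue  # untransformable curve, excluded
        norm = normalize_to_reference(test_means, ref_means)
        test_dense = interpolate_circular(test_h, norm)
        trial_h = sub["heading_deg"].to_numpy(dtype=float)
        trial_r = sub["rate_sps"].to_numpy(dtype=float)
        for half in HALVES:
            p, gated = half_tuning_gate(trial_h, trial_r, half, alpha)
            if collect is not None:
                collect.gate_pvalues[(half, direction)] = p
                collect.gated[(half, direction)] = gated
            if not gated:
                continue
            lag = partial_shift(ref_dense, test_dense, half, window_deg)
            shifts[(half, direction)] = lag
    if collect is not None:
        collect.partial_shifts = dict(shifts)
    if not shifts:
        return None
    return mean_shift(shifts, mode, preference_deg)


def estimate_shift(
    trials: pd.DataFrame,
    neuron_id: object,
    condition_type: str = "SP",
    n_boot: int = 300,
    seed: int | None = None,
    alpha: float = 0.05,
    window_deg: int = DEFAULT_SEARCH_WINDOW_DEG,
    mode: str = "signed",
    preference_deg: float | None = None,
) -> ShiftResult:
    """Partial-shift analysis with percentile-bootstrap CI for one neuron.

    ``trials`` follows the trial-table schema (columns neuron_id,
    condition, heading_deg, repetition, rate_sps). ``condition_type`` is
    "RP" or "SP". ``n_boot=0`` skips the bootstrap. ``preference_deg``
    overrides the data-estimated preferred heading used by the signed
    alignment (useful when ground truth is known, e.g. simulations).
    """
    df = trials[trials["neuron_id"] == neuron_id]
    if df.empty:
        raise ValueError(f"no trials for neuron {neuron_id!r}")
    result = ShiftResult(neuron_id=neuron_id, condition_type=condition_type)
    result.mean_shift = _shift_once(
        df, condition_type, alpha, window_deg, mode, result, preference_deg
    )
    if n_boot > 0 and result.mean_shift is not None:
        rng = np.random.default_rng(seed)
        boots = bootstrap_shifts(
            df, condition_type, n_boot, rng, alpha, window_deg, mode, preference_deg
        )
        result.n_boot = n_boot
        result.n_boot_dropped = n_boot - len(boots)
        if len(boots) > 0:
            lo, hi = np.percentile(boots, [2.5, 97.5])
            result.ci95 = (float(lo), float(hi))
    return result


_STANDARD_HEADINGS = np.arange(0.0, 360.0, 45.0)

# linear-interpolation stencil from the 45° grid to the 1° grid
_DENSE_GRID = np.arange(360)
_SEG = _DENSE_GRID // 45
_FRAC = (_DENSE_GRID % 45) / 45.0
_SEG_NEXT = (_SEG + 1) % 8

_INTERIOR_IDX = {"forward": np.array([1, 2, 3]), "backward": np.array([5, 6, 7])}

_LAG_CACHE: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}


def _lag_stencil(half: str, window_deg: int) -> tuple[np.ndarray, np.ndarray]:
    key = (half, window_deg)
    if key not in _LAG_CACHE:
        support = _half_support(half)
        lags = np.arange(-window_deg, window_deg + 1)
        _LAG_CACHE[key] = (lags, (support[None, :] - lags[:, None]) % 360)
    return _LAG_CACHE[key]


def _interp45(means8: np.ndarray) -> np.ndarray:
    """1° piecewise-linear interpolation of an 8-point 45°-grid curve."""
    return means8[_SEG] * (1.0 - _FRAC) + means8[_SEG_NEXT] * _FRAC


def _anova_p(groups: list[np.ndarray]) -> float:
    """One-way ANOVA p-value on small groups (manual F computation)."""
    k = len(groups)
    ns = np.array([g.size for g in groups])
    if k < 2 or np.any(ns < 2):
        return np.nan
    n_tot = ns.sum()
    gms = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float((ns * (gms - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, gms)))
    if ssw == 0.0:
        return 0.0 if ssb > 0 else np.nan
    F = (ssb / (k - 1)) / (ssw / (n_tot - k))
    return float(stats.f.sf(F, k - 1, n_tot - k))


def bootstrap_shifts(
    df: pd.DataFrame,
    condition_type: str,
    n_boot: int,
    rng: np.random.Generator,
    alpha: float = 0.05,
    window_deg: int = DEFAULT_SEARCH_WINDOW_DEG,
    mode: str = "signed",
    preference_deg: float | None = None,
) -> np.ndarray:
    """Bootstrap distribution of the mean shift for one neuron.

    Trials are resampled with replacement within each heading × condition
    cell (stratified, preserving the design), and the full pipeline is
    rerun per replicate. Replicates with no gated half are dropped. For
    the standard 8 × 45° heading grid a vectorized numpy path is used;
    other designs fall back to the general pipeline.
    """
    conds = ["translation_only", f"{condition_type}_left", f"{condition_type}_right"]
    cells: dict[str, list[np.ndarray]] = {}
    for cond in conds:
        sub = df[df["condition"] == cond]
        per_heading = {
            h: g["rate_sps"].to_numpy(dtype=float)
            for h, g in sub.groupby("heading_deg")
        }
        hs = np.array(sorted(per_heading))
        if not np.array_equal(hs, _STANDARD_HEADINGS):
            return _bootstrap_shifts_slow(
                df, condition_type, n_boot, rng, alpha, window_deg, mode,
                preference_deg,
            )
        cells[cond] = [per_heading[h] for h in hs]

    out = []
    directions = ("left", "right")
    for _ in range(n_boot):
        res = {
            cond: [g[rng.integers(0, g.size, g.size)] for g in gs]
            for cond, gs in cells.items()
        }
        ref_means = np.array([g.mean() for g in res["translation_only"]])
        ref_range = np.ptp(ref_means)
        if ref_range == 0:
            continue
        ref_dense = _interp45(ref_means)
        pref = (
            preference_deg
            if preference_deg is not None
            else float(np.argmax(ref_dense))
        )
        shifts: dict[tuple[str, str], float] = {}
        for direction in directions:
            groups = res[f"{condition_type}_{direction}"]
            test_means = np.array([g.mean() for g in groups])
            if np.ptp(test_means) == 0:
                continue
            norm = (test_means - test_means.min()) * (
                ref_range / np.ptp(test_means)
            ) + ref_means.min()
            test_dense = _interp45(norm)
            for half in HALVES:
                p = _anova_p([groups[i] for i in _INTERIOR_IDX[half]])
                if not (np.isfinite(p) and p <= alpha):
                    continue
                lags, idx = _lag_stencil(half, window_deg)
                support = _half_support(half)
                sse = ((ref_dense[idx] - test_dense[support][None, :]) ** 2).sum(axis=1)
                best = np.lexsort((lags, np.abs(lags), sse))[0]
                shifts[(half, direction)] = int(lags[best])
        if shifts:
            out.append(mean_shift(shifts, mode, pref))
    return np.asarray(out, dtype=float)


def _bootstrap_shifts_slow(
    df: pd.DataFrame,
    condition_type: str,
    n_boot: int,
    rng: np.random.Generator,
    alpha: float,
    window_deg: int,
    mode: str,
    preference_deg: float | None,
) -> np.ndarray:
    conds = ["translation_only", f"{condition_type}_left", f"{condition_type}_right"]
    cells = []
    for cond in conds:
        sub = df[df["condition"] == cond]
        for h, g in sub.groupby("heading_deg"):
            cells.append((cond, h, g["rate_sps"].to_numpy(dtype=float)))
    out = []
    for _ in range(n_boot):
        rows_cond, rows_h, rows_r = [], [], []
        for cond, h, rates in cells:
            take = rng.integers(0, len(rates), size=len(rates))
            rows_cond.extend([cond] * len(rates))
            rows_h.extend([h] * len(rates))
            rows_r.extend(rates[take])
        rep = pd.DataFrame(
            {"condition": rows_cond, "heading_deg": rows_h, "rate_sps": rows_r}
        )
        try:
            s = _shift_once(
                rep, condition_type, alpha, window_deg, mode,
                preference_deg=preference_deg,
            )
        except ValueError:
            s = None
        if s is not None:
            out.append(s)
    return np.asarray(out, dtype=float)


def estimate_shifts_population(
    trials: pd.DataFrame,
    condition_types: tuple[str, ...] = ("RP", "SP"),
    n_boot: int = 300,
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`estimate_shift` for every neuron × condition type.

    Returns a table with one row per neuron/condition: mean shift, CI
    bounds, number of gated halves. Neurons whose shift is undefined (no
    gated half) get NaN shifts and are flagged.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    neuron_ids = sorted(trials["neuron_id"].unique())
    child_seeds = ss.spawn(len(neuron_ids) * len(condition_types))
    i = 0
    for nid in neuron_ids:
        for ct in condition_types:
            if not (trials["condition"] == f"{ct}_left").any() and not (
                trials["condition"] == f"{ct}_right"
            ).any():
                i += 1
                continue
            res = estimate_shift(
                trials,
                nid,
                condition_type=ct,
                n_boot=n_boot,
                seed=child_seeds[i].generate_state(1)[0] % (2**31),
                **kwargs,
            )
            i += 1
            rows.append(
                {
                    "neuron_id": nid,
                    "condition": ct,
                    "mean_shift_deg": res.mean_shift,
                    "ci_lo": res.ci95[0] if res.ci95 else np.nan,
                    "ci_hi": res.ci95[1] if res.ci95 else np.nan,
                    "n_gated_halves": res.n_gated_halves,
                    "n_boot_dropped": res.n_boot_dropped,
                }
            )
    return pd.DataFrame(rows)
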