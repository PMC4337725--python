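"""Population-level statistics: bandwidths, compensation classes, rotation responses.

Builds on the per-neuron shift estimates: full width at half height (FWHH)
of interpolated tuning curves, bandwidth-change tests for lateral-preferring
neurons, classification of each neuron's rotation compensation from its
bootstrap CI, population medians with nonparametric tests, and the analysis
of responses to pure-rotation control conditions (pursuit in darkness vs
visually simulated rotation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .shift_analysis import ShiftResult, interpolate_circular


def fwhh(dense_curve: np.ndarray, step_deg: float = 1.0) -> float:
    """Full width at half height (deg) of a circular tuning curve.

    Half height is (min + max)/2. The width is that of the longest
    contiguous circular arc at or above half height, with the two crossing
    points located by linear interpolation. A flat curve has no width.
    """
    v = np.asarray(dense_curve, dtype=float)
    n = v.size
    if np.ptp(v) == 0:
        raise ValueError("FWHH undefined for a flat curve")
    half = (v.min() + v.max()) / 2.0
    above = v >= half
    # find runs of consecutive supra-half samples on the circle
    idx = np.flatnonzero(above)
    if idx.size == n:  # cannot happen: min < half by construction
        return 360.0
    # rotate so position 0 is below half, making runs non-wrapping
    start = int(np.flatnonzero(~above)[0])
    above_r = np.roll(above, -start)
    v_r = np.roll(v, -start)
    d = np.diff(above_r.astype(int))
    run_starts = np.flatnonzero(d == 1) + 1
    run_ends = np.flatnonzero(d == -1) + 1  # exclusive
    if above_r[-1]:
        run_ends = np.append(run_ends, n)
    widths = []
    for s, e in zip(run_starts, run_ends):
        # interpolate the crossing before s and after e-1
        lo = s - 1
        frac_lo = (half - v_r[lo]) / (v_r[s] - v_r[lo])
        left = lo + frac_lo
        hi = e % n
        frac_hi = (v_r[e - 1] - half) / (v_r[e - 1] - v_r[hi])
        right = (e - 1) + frac_hi
        widths.append((right - left) * step_deg)
    return float(max(widths))


def curve_fwhh(headings_deg: np.ndarray, means: np.ndarray) -> float:
    """FWHH of a sampled tuning curve after 1° circular interpolation."""
    return fwhh(interpolate_circular(headings_deg, means))


def bandwidth_change_test(
    delta_fwhh_0: np.ndarray, delta_fwhh_180: np.ndarray
) -> tuple[float, float, float]:
    """Rank-sum test of bandwidth changes between lateral preference groups.

    ``delta_fwhh_0`` holds FWHH(rotation-added) − FWHH(pure translation)
    for 0°-preferring neurons, ``delta_fwhh_180`` likewise for
    180°-preferring neurons, for one rotation direction. Returns
    (p-value, mean Δ of the 0° group, mean Δ of the 180° group).
    """
    a = np.asarray(delta_fwhh_0, dtype=float)
    b = np.asarray(delta_fwhh_180, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 neurons per preference group")
    _, p = stats.ranksums(a, b)
    return float(p), float(a.mean()), float(b.mean())


def classify_compensation(
    result: ShiftResult | tuple[float, float],
    reference_shift_deg: float = 20.0,
    rule: str = "cloud",
) -> str:
    """Compensation class from the bootstrap CI of the mean shift.

    - ``invariant``: CI contains 0 (rotation-invariant tuning)
    - ``over``: CI entirely below 0 (over-compensation)
    - ``none``: shift consistent with responding to the resultant flow —
      for the cloud stimulus, CI entirely above the reference shift; for
      the approaching-plane stimulus (``rule='fp'``), CI containing or
      exceeding the reference
    - ``partial``: everything else
    """
    ci = result.ci95 if isinstance(result, ShiftResult) else tuple(result)
    if ci is None:
        raise ValueError("classification requires a confidence interval")
    lo, hi = ci
    if lo <= 0.0 <= hi:
        return "invariant"
    if hi < 0.0:
        return "over"
    if rule == "cloud":
        if lo > reference_shift_deg:
            return "none"
    elif rule == "fp":
        if hi >= reference_shift_deg:
            return "none"
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return "partial"


def population_summary(
    table: pd.DataFrame, reference_shift_deg: float = 20.0
) -> dict[str, float]:
    """Medians and nonparametric tests over the per-neuron shift table.

    ``table`` is the output of ``estimate_shifts_population`` with paired
    RP and SP rows per neuron. Unpaired neurons are dropped. Returns
    medians, the paired signed-rank p for RP vs SP, signed-rank ps vs 0
    and vs the reference shift, and the median RP−SP difference.
    """
    wide = table.pivot_table(
        index="neuron_id", columns="condition", values="mean_shift_deg"
    ).dropna()
    if not {"RP", "SP"}.issubset(wide.columns):
        raise ValueError("table must contain paired RP and SP rows")
    rp = wide["RP"].to_numpy()
    sp = wide["SP"].to_numpy()
    out = {
        "n_pairs": int(len(wide)),
        "median_rp_deg": float(np.median(rp)),
        "median_sp_deg": float(np.median(sp)),
        "median_diff_deg": float(np.median(rp - sp)),
    }
    diff = rp - sp
    out["p_rp_vs_sp"] = 1.0 if np.allclose(diff, 0) else float(
        stats.wilcoxon(rp, sp).pvalue
    )
    for name, x in (("rp", rp), ("sp", sp)):
        out[f"p_{name}_vs_0"] = (
            1.0 if np.allclose(x, 0) else float(stats.wilcoxon(x).pvalue)
        )
        shifted = x - reference_shift_deg
        out[f"p_{name}_vs_ref"] = (
            1.0 if np.allclose(shifted, 0) else float(stats.wilcoxon(shifted).pvalue)
        )
    return out


def rotation_response_analysis(
    trials: pd.DataFrame,
    baseline_condition: str = "blank",
    alpha: float = 0.05,
    test: str = "ttest",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Responses to pure-rotation controls and their cross-condition link.

    For every neuron and rotation direction, the mean baseline-subtracted
    response to pursuit-in-darkness and to visually simulated rotation is
    computed with a per-neuron significance flag (t-test against the
    baseline trials by default; ``test='wilcoxon'`` for the rank-sum
    variant). Population-level Spearman rank correlations are computed
    between the two rotation types per direction and for the
    leftward−rightward difference.

    Returns (per-neuron table, summary dict of correlations/p-values).
    """
    pairs = {"pursuit_dark": "pursuit_dark", "sim_rotation": "sim_rotation"}
    rows = []
    for nid, df in trials.groupby("neuron_id"):
        base = df[df["condition"] == baseline_condition]["rate_sps"].to_numpy()
        if base.size == 0:
            raise ValueError(f"missing baseline trials for neuron {nid!r}")
        row: dict[str, object] = {"neuron_id": nid, "baseline_sps": float(base.mean())}
        for stim in pairs:
            for direction in ("left", "right"):
                resp = df[df["condition"] == f"{stim}_{direction}"][
                    "rate_sps"
                ].to_numpy()
                if resp.size == 0:
                    continue
                delta = float(resp.mean() - base.mean())
                if test == "ttest":
                    p = float(stats.ttest_ind(resp, base, equal_var=False).pvalue)
                elif test == "wilcoxon":
                    p = float(stats.ranksums(resp, base).pvalue)
                else:
                    raise ValueError(f"unknown test {test!r}")
                row[f"{stim}_{direction}_sps"] = delta
                row[f"{stim}_{direction}_p"] = p
                row[f"{stim}_{direction}_sig"] = p <= alpha
        rows.append(row)
    per = pd.DataFrame(rows)
    summary: dict[str, float] = {}
    for direction in ("left", "right"):
        a = per.get(f"pursuit_dark_{direction}_sps")
        b = per.get(f"sim_rotation_{direction}_sps")
        if a is None or b is None:
            continue
        r, p = stats.spearmanr(a, b)
        summary[f"spearman_{direction}"] = float(r)
        summary[f"spearman_{direction}_p"] = float(p)
    if {"pursuit_dark_left_sps", "pursuit_dark_right_sps"}.issubset(per.columns):
        d_dark = per["pursuit_dark_left_sps"] - per["pursuit_dark_right_sps"]
        d_sim = per["sim_rotation_left_sps"] - per["sim_rotation_right_sps"]
        per["pursuit_dark_LR_sps"] = d_dark
        per["sim_rotation_LR_sps"] = d_sim
        r, p = stats.spearmanr(d_dark, d_sim)
        summary["spearman_LR"] = float(r)
        summary["spearman_LR_p"] = float(p)
    return per, summary
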