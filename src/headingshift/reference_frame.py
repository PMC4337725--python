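"""Temporal-slope analysis dissociating reference frame from rotation invariance.

During pursuit the eye-centered reference frame rotates relative to the
heading, so for a neuron coding heading in eye coordinates the firing rate
at a fixed heading drifts over the trial: upward for rotations that carry
the eye up the tuning slope, downward for the opposite direction. The
predicted eye-centered slope is the tuning-curve gradient at the heading of
largest positive gradient times the rotation speed; the measured population
slope, as a fraction of that prediction, estimates where the representation
sits between head-centered (0) and eye-centered (1).

Pipeline: per neuron and condition, select the heading with the largest
positive circular gradient (excluding curves whose response there is not
significantly different from both neighbors); smooth the spike trains at
that heading with a 25 ms Gaussian kernel; normalize by the neuron's
pure-translation dynamic range; average across neurons; regress the mean
trace on time over the 375–1125 ms plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .protocol import PLATEAU_END_MS, PLATEAU_START_MS, ProtocolSpec

KERNEL_SIGMA_MS = 25.0


@dataclass
class GradientSelection:
    heading_deg: float
    gradient_per_deg: float  # at the selected heading, raw rate units
    included: bool
    reason: str = ""


@dataclass
class SlopeResult:
    condition: str  # e.g. "RP_right", "translation_only"
    measured_slope_per_s: float
    ci95: tuple[float, float]
    predicted_slope_per_s: float | None
    n_traces: int


def circular_gradient(means: np.ndarray, step_deg: float = 45.0) -> np.ndarray:
    """Central-difference gradient (rate per degree) on the circular grid."""
    m = np.asarray(means, dtype=float)
    return (np.roll(m, -1) - np.roll(m, 1)) / (2.0 * step_deg)


def max_gradient_heading(
    headings_deg: np.ndarray,
    trial_rates: pd.DataFrame,
    alpha: float = 0.05,
) -> GradientSelection:
    """Heading with the largest positive tuning gradient, with exclusion.

    ``trial_rates`` has columns heading_deg, rate_sps (one row per trial).
    The selected heading is excluded when its mean response is not
    significantly different (t-test, p ≤ alpha) from both immediate
    neighbors — the largest measured gradient may then sit on a peak or
    trough between samples.
    """
    h = np.asarray(headings_deg, dtype=float)
    order = np.argsort(h)
    h = h[order]
    means = np.array(
        [trial_rates[trial_rates["heading_deg"] == hh]["rate_sps"].mean() for hh in h]
    )
    if np.ptp(means) == 0:
        return GradientSelection(np.nan, 0.0, False, "flat curve")
    step = 360.0 / len(h)
    grad = circular_gradient(means, step)
    i = int(np.argmax(grad))
    if grad[i] <= 0:
        return GradientSelection(np.nan, 0.0, False, "no positive gradient")
    sel = h[i]
    x = trial_rates[trial_rates["heading_deg"] == sel]["rate_sps"].to_numpy()
    ok = True
    for j in ((i - 1) % len(h), (i + 1) % len(h)):
        y = trial_rates[trial_rates["heading_deg"] == h[j]]["rate_sps"].to_numpy()
        if x.size < 2 or y.size < 2:
            ok = False
            break
        p = stats.ttest_ind(x, y, equal_var=False).pvalue
        if not (p <= alpha):
            ok = False
            break
    return GradientSelection(
        float(sel), float(grad[i]), ok, "" if ok else "not distinct from neighbors"
    )


def smooth_rate(
    spike_times_ms: np.ndarray,
    trial_duration_ms: float = 1500.0,
    kernel_sigma_ms: float = KERNEL_SIGMA_MS,
    dt_ms: float = 1.0,
) -> np.ndarray:
    """Firing-rate trace (spikes/s) from spike events, Gaussian-smoothed.

    Spikes are binned at ``dt_ms``, convolved with a Gaussian kernel of the
    given σ, and edge-corrected by the kernel mass inside the trial so that
    the trace integral approximates the spike count.
    """
    n = int(round(trial_duration_ms / dt_ms))
    t = np.asarray(spike_times_ms, dtype=float)
    if np.any((t < 0) | (t > trial_duration_ms)):
        raise ValueError("spike times outside the trial")
    counts, _ = np.histogram(t, bins=n, range=(0.0, trial_duration_ms))
    sigma_bins = kernel_sigma_ms / dt_ms
    num = gaussian_filter1d(counts.astype(float), sigma_bins, mode="constant")
    den = gaussian_filter1d(np.ones(n), sigma_bins, mode="constant")
    return num / den / (dt_ms / 1000.0)


def predicted_slope_per_s(
    gradients_per_unit: np.ndarray, omega_deg_s: float, rotation_dir: str
) -> float:
    """Eye-centered prediction: mean normalized gradient × rotation speed.

    ``gradients_per_unit`` are tuning gradients per degree of curves
    normalized to unit range; rightward rotation carries the eye up the
    positive gradient (positive slope), leftward down.
    """
    sign = 1.0 if rotation_dir == "right" else -1.0
    return sign * float(np.mean(gradients_per_unit)) * omega_deg_s


def _plateau_mask(n: int, dt_ms: float = 1.0) -> np.ndarray:
    t = (np.arange(n) + 0.5) * dt_ms
    return (t >= PLATEAU_START_MS) & (t <= PLATEAU_END_MS)


def population_slope(
    traces: list[np.ndarray],
    dt_ms: float = 1.0,
    min_traces: int = 5,
) -> tuple[float, tuple[float, float]]:
    """Slope (per s) of the across-neuron mean trace over the plateau.

    ``traces`` are per-neuron normalized rate traces on a common time grid.
    The population slope is the OLS slope of the mean trace (identical to
    the mean of the per-trace slopes); its 95% CI comes from the
    across-neuron dispersion of per-trace slopes, since the smoothed trace
    samples are serially correlated and the regression's own standard
    error would be far too optimistic.
    """
    if len(traces) < min_traces:
        raise ValueError(f"need at least {min_traces} traces")
    X = np.stack(traces)
    mask = _plateau_mask(X.shape[1], dt_ms)
    t_s = ((np.arange(X.shape[1]) + 0.5) * dt_ms / 1000.0)[mask]
    tc = t_s - t_s.mean()
    y = X[:, mask]
    slopes = (y - y.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)
    slope = float(slopes.mean())
    sem = float(slopes.std(ddof=1) / np.sqrt(len(slopes)))
    return slope, (slope - 1.96 * sem, slope + 1.96 * sem)


def _fitted_gradient_per_deg(
    headings_deg: np.ndarray, means: np.ndarray, at_deg: float
) -> float | None:
    """Analytic tuning-curve derivative at ``at_deg`` from a von Mises fit.

    The 45° central difference smooths the derivative over a 90° window
    and under-reads the true slope of a concentrated tuning curve, which
    biases measured/predicted slope ratios upward. Fitting the von Mises
    family to the 8 sampled means and differentiating analytically removes
    that discretization bias. Returns None when the fit fails.
    """
    from scipy.optimize import curve_fit

    h = np.asarray(headings_deg, dtype=float)
    m = np.asarray(means, dtype=float)

    def model(theta, A, phi, k, b):
        return b + A * np.exp(k * (np.cos(np.radians(theta - phi)) - 1.0))

    try:
        p0 = (np.ptp(m), h[np.argmax(m)], 2.0, m.min())
        popt, _ = curve_fit(
            model, h, m, p0=p0,
            bounds=([1e-6, -360, 0.2, -np.inf], [np.inf, 720, 20, np.inf]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return None
    A, phi, k, _ = popt
    d = np.radians(at_deg - phi)
    # d/dθ in per-degree units
    return float(-A * k * np.sin(d) * np.exp(k * (np.cos(d) - 1.0)) * np.pi / 180.0)


def analyze_reference_frame(
    trials: pd.DataFrame,
    spikes: pd.DataFrame,
    protocol: ProtocolSpec = ProtocolSpec(),
    alpha: float = 0.05,
    min_traces: int = 5,
) -> pd.DataFrame:
    """Full temporal reference-frame analysis over a recorded population.

    For every neuron × condition, the largest-gradient heading is selected
    from that condition's tuning curve (with the neighbor-distinctness
    exclusion); the spike trains at that heading are kernel-smoothed,
    averaged over repetitions, and normalized by the neuron's
    pure-translation dynamic range. Traces are averaged across neurons per
    condition and regressed on time over the plateau. The eye-centered
    prediction per rotation condition is the population-mean normalized
    gradient times the rotation speed.

    Returns one row per condition with measured slope, CI, prediction and
    trace count.
    """
    conditions = [c for c in trials["condition"].unique() if c == "translation_only"
                  or c.startswith(("RP_", "SP_"))]
    rows = []
    for cond in sorted(conditions):
        cond_traces: list[np.ndarray] = []
        gradients: list[float] = []
        gradients_fit: list[float] = []
        for nid, df in trials[trials["condition"] == cond].groupby("neuron_id"):
            tr_df = trials[
                (trials["neuron_id"] == nid)
                & (trials["condition"] == "translation_only")
            ]
            rng_range = (
                tr_df.groupby("heading_deg")["rate_sps"].mean().max()
                - tr_df.groupby("heading_deg")["rate_sps"].mean().min()
            )
            if rng_range <= 0:
                continue
            sel = max_gradient_heading(
                df["heading_deg"].unique(), df[["heading_deg", "rate_sps"]], alpha
            )
            if not sel.included:
                continue
            spk = spikes[
                (spikes["neuron_id"] == nid)
                & (spikes["condition"] == cond)
                & (spikes["heading_deg"] == sel.heading_deg)
            ]
            if spk.empty and not (
                spikes["neuron_id"].eq(nid) & spikes["condition"].eq(cond)
            ).any():
                continue
            reps = trials[
                (trials["neuron_id"] == nid) & (trials["condition"] == cond)
            ]["repetition"].unique()
            rep_traces = []
            for r in reps:
                times = spk[spk["repetition"] == r]["t_ms"].to_numpy()
                rep_traces.append(
                    smooth_rate(times, protocol.trial_duration_ms)
                )
            if not rep_traces:
                continue
            cond_traces.append(np.mean(rep_traces, axis=0) / rng_range)
            gradients.append(sel.gradient_per_deg / rng_range)
            cond_means = df.groupby("heading_deg")["rate_sps"].mean()
            gfit = _fitted_gradient_per_deg(
                cond_means.index.to_numpy(), cond_means.to_numpy(), sel.heading_deg
            )
            gradients_fit.append(
                gfit / rng_range if gfit is not None else sel.gradient_per_deg / rng_range
            )
        if len(cond_traces) < min_traces:
            continue
        slope, ci = population_slope(cond_traces, min_traces=min_traces)
        if cond == "translation_only":
            predicted = predicted_fit = 0.0
        else:
            direction = cond.rsplit("_", 1)[1]
            predicted = predicted_slope_per_s(
                np.asarray(gradients), protocol.rotation_peak_deg_s, direction
            )
            predicted_fit = predicted_slope_per_s(
                np.asarray(gradients_fit), protocol.rotation_peak_deg_s, direction
            )
        rows.append(
            {
                "condition": cond,
                "measured_slope_per_s": slope,
                "ci_lo": ci[0],
                "ci_hi": ci[1],
                "predicted_slope_per_s": predicted,
                "predicted_slope_fit_per_s": predicted_fit,
                "n_traces": len(cond_traces),
            }
        )
    return pd.DataFrame(rows)


def frame_weight_estimate(result: pd.DataFrame) -> float:
    """Measured/predicted slope ratio pooled over rotation conditions (λ̂).

    Uses the fit-based (discretization-unbiased) prediction when present,
    the central-difference prediction otherwise.
    """
    col = (
        "predicted_slope_fit_per_s"
        if "predicted_slope_fit_per_s" in result.columns
        else "predicted_slope_per_s"
    )
    rot = result[result["condition"] != "translation_only"]
    rot = rot[np.abs(rot[col]) > 0]
    if rot.empty:
        raise ValueError("no rotation conditions with a nonzero prediction")
    ratios = rot["measured_slope_per_s"] / rot[col]
    return float(np.mean(ratios))
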