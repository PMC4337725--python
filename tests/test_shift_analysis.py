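import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from headingshift.shift_analysis import (
    SIGN_TABLE,
    alignment_sign,
    bootstrap_shifts,
    estimate_shift,
    half_tuning_gate,
    interpolate_circular,
    mean_shift,
    normalize_to_reference,
    partial_shift,
)
from headingshift.synthetic_neurons import (
    NeuronSpec,
    VonMisesParams,
    simulate_trials,
    vm,
)

H8 = np.arange(0.0, 360.0, 45.0)


def brute_force_partial_shift(ref_dense, test_dense, half, window=90):
    """Independent oracle: plain-python exhaustive SSE search."""
    if half == "forward":
        support = list(range(0, 181))
    else:
        support = list(range(180, 360)) + [0]
    best_lag, best_sse = None, None
    for lag in range(-window, window + 1):
        sse = sum(
            (ref_dense[(theta - lag) % 360] - test_dense[theta]) ** 2
            for theta in support
        )
        if (
            best_sse is None
            or sse < best_sse
            or (sse == best_sse and abs(lag) < abs(best_lag))
        ):
            best_lag, best_sse = lag, sse
    return best_lag


class TestNormalization:
    def test_identity(self):
        ref = vm(H8, VonMisesParams())
        assert np.allclose(normalize_to_reference(ref, ref), ref)

    def test_affine_inversion(self):
        ref = vm(H8, VonMisesParams())
        test = 2.0 * ref + 5.0
        assert np.allclose(normalize_to_reference(test, ref), ref)

    @given(
        arrays(np.float64, 8, elements=st.floats(0, 100)),
        arrays(np.float64, 8, elements=st.floats(0, 100)),
    )
    def test_min_and_range_match_reference(self, test, ref):
        if np.ptp(ref) == 0 or np.ptp(test) == 0:
            with pytest.raises(ValueError):
                normalize_to_reference(test, ref)
            return
        out = normalize_to_reference(test, ref)
        assert out.min() == pytest.approx(ref.min(), abs=1e-9)
        assert np.ptp(out) == pytest.approx(np.ptp(ref), rel=1e-12)
        # shape preserved: a positive affine map is monotone (ties may be
        # introduced only by floating-point absorption of tiny differences)
        for i in range(8):
            for j in range(8):
                if test[i] < test[j]:
                    assert out[i] <= out[j]


class TestGate:
    def test_constant_trials_not_gated(self):
        h = np.repeat(H8, 5)
        r = np.full(h.size, 12.0)
        p, gated = half_tuning_gate(h, r, "forward")
        assert not gated

    def test_strong_tuning_gated(self):
        """A = 50 over baseline 5 passes the boundary-inclusive gate in
        virtually every draw; the interior-only default (3 groups, less
        power) still passes in the large majority."""
        n_full = n_interior = 0
        for seed in range(50):
            neuron = NeuronSpec(
                base=VonMisesParams(A=50.0, phi_deg=90.0, k=2.0), baseline_sps=5.0
            )
            tr = simulate_trials(neuron, reps=5, seed=seed)
            sub = tr[tr["condition"] == "SP_right"]
            h = sub["heading_deg"].to_numpy()
            r = sub["rate_sps"].to_numpy()
            n_full += half_tuning_gate(h, r, "forward", interior_only=False)[1]
            n_interior += half_tuning_gate(h, r, "forward")[1]
        assert n_full >= 49
        assert n_interior >= 40

    def test_insufficient_trials_not_gated(self):
        p, gated = half_tuning_gate(np.array([45.0, 90.0]), np.array([1.0, 2.0]),
                                    "forward")
        assert not gated and np.isnan(p)

    def test_boundary_headings_belong_to_both_fit_supports(self):
        from headingshift.shift_analysis import half_headings

        for h in (0.0, 180.0, 360.0):
            assert half_headings(np.array([h]), "forward")[0]
            assert half_headings(np.array([h]), "backward")[0]


class TestInterpolation:
    def test_sample_points_unchanged(self):
        v = np.array([3.0, 9.0, 1.0, 7.0, 2.0, 8.0, 4.0, 6.0])
        dense = interpolate_circular(H8, v)
        assert np.allclose(dense[::45], v)

    def test_midpoint_linearity(self):
        v = np.arange(8.0)
        dense = interpolate_circular(H8, v)
        assert dense[22] == pytest.approx((22.5 / 45) * 1.0, abs=0.03)
        # exact midpoint at 22.5° is between grid points; check 22 and 23
        assert (dense[22] + dense[23]) / 2 == pytest.approx(0.5, abs=0.02)

    def test_wraparound_midpoint(self):
        v = np.zeros(8)
        v[0], v[7] = 10.0, 4.0  # values at 0° and 315°
        dense = interpolate_circular(H8, v)
        # 337.5° is halfway between 315° and 360°(=0°)
        assert (dense[337] + dense[338]) / 2 == pytest.approx(7.0, abs=0.1)

    def test_duplicate_headings_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            interpolate_circular(np.array([0.0, 0.0, 90.0]), np.zeros(3))


class TestPartialShift:
    def test_identity_zero_lag(self):
        ref = interpolate_circular(H8, vm(H8, VonMisesParams()))
        assert partial_shift(ref, ref, "forward") == 0
        assert partial_shift(ref, ref, "backward") == 0

    @pytest.mark.parametrize("lag", [-60, -20, 1, 20, 45, 89])
    def test_rolled_reference_recovered_exactly(self, lag):
        """A global rotation of the dense curve is recovered at ±0°."""
        rng = np.random.default_rng(4)
        ref = interpolate_circular(H8, rng.uniform(0, 50, 8))
        test = np.roll(ref, lag)
        assert partial_shift(ref, test, "forward") == lag
        assert partial_shift(ref, test, "backward") == lag

    def test_matches_brute_force_oracle(self):
        """Vectorized search equals the exhaustive python oracle, 200 draws."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            ref = interpolate_circular(H8, rng.uniform(0, 60, 8))
            test = interpolate_circular(H8, rng.uniform(0, 60, 8))
            half = "forward" if rng.random() < 0.5 else "backward"
            assert partial_shift(ref, test, half) == brute_force_partial_shift(
                list(ref), list(test), half
            )

    def test_flat_reference_rejected(self):
        flat = np.full(360, 7.0)
        with pytest.raises(ValueError, match="flat"):
            partial_shift(flat, flat, "forward")


class TestMeanShift:
    def test_four_aligned_twenties(self):
        shifts = {(h, d): alignment_sign(h, d, 90.0) * 20.0
                  for h in ("forward", "backward") for d in ("left", "right")}
        assert mean_shift(shifts, "signed", 90.0) == pytest.approx(20.0)

    def test_lateral_sign_table_cells(self):
        assert alignment_sign("forward", "right", 0.0) == SIGN_TABLE[("forward", "right")] == 1
        assert alignment_sign("forward", "left", 0.0) == -1
        assert alignment_sign("backward", "right", 180.0) == -1
        assert alignment_sign("backward", "left", 180.0) == 1

    def test_foreaft_preference_alignment(self):
        # forward-preferring: both halves share the preference's sign
        assert alignment_sign("forward", "right", 90.0) == 1
        assert alignment_sign("backward", "right", 90.0) == 1
        assert alignment_sign("forward", "left", 90.0) == -1
        # backward-preferring mirrors
        assert alignment_sign("forward", "right", 270.0) == -1

    def test_absolute_mode(self):
        shifts = {("forward", "right"): 20, ("backward", "right"): -20}
        assert mean_shift(shifts, "absolute") == pytest.approx(20.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_shift({}, "signed", 90.0)


def _noiseless_neuron(c, phi=100.0, seed=0):
    neuron = NeuronSpec(
        base=VonMisesParams(A=60.0, phi_deg=phi, k=3.0),
        c_rp=c, c_sp=c, baseline_sps=0.0,
        gain_range=(1.0, 1.0), offset_range=(0.0, 0.0),
    )
    return simulate_trials(neuron, reps=5, seed=seed, noise=False)


class TestEstimatePipeline:
    def test_invariant_neuron_scores_zero(self):
        tr = _noiseless_neuron(c=1.0)
        r = estimate_shift(tr, 0, "SP", n_boot=0, preference_deg=100.0)
        assert r.mean_shift == pytest.approx(0.0, abs=0.5)

    def test_uncompensated_neuron_scores_twenty(self):
        tr = _noiseless_neuron(c=0.0)
        r = estimate_shift(tr, 0, "SP", n_boot=0, preference_deg=100.0)
        assert r.mean_shift == pytest.approx(20.0, abs=1.0)

    def test_affine_nuisance_leaves_noiseless_shift_unchanged(self):
        """Gain 0.66–1.33 and offset 0–40 are removed by normalization."""
        base = estimate_shift(_noiseless_neuron(0.0, seed=1), 0, "SP", n_boot=0,
                              preference_deg=100.0)
        neuron = NeuronSpec(
            base=VonMisesParams(A=60.0, phi_deg=100.0, k=3.0),
            c_rp=0.0, c_sp=0.0, baseline_sps=0.0,
            gain_range=(0.66, 1.33), offset_range=(0.0, 40.0),
        )
        tr = simulate_trials(neuron, reps=5, seed=1, noise=False)
        r = estimate_shift(tr, 0, "SP", n_boot=0, preference_deg=100.0)
        assert r.mean_shift == base.mean_shift

    def test_bootstrap_deterministic_under_seed(self):
        neuron = NeuronSpec(base=VonMisesParams(A=60.0, phi_deg=100.0, k=3.0),
                            c_sp=0.0, c_rp=0.0)
        tr = simulate_trials(neuron, reps=5, seed=9)
        a = estimate_shift(tr, 0, "SP", n_boot=50, seed=123)
        b = estimate_shift(tr, 0, "SP", n_boot=50, seed=123)
        assert a.ci95 == b.ci95

    def test_zero_variance_trials_give_zero_width_ci(self):
        tr = _noiseless_neuron(c=0.0)
        r = estimate_shift(tr, 0, "SP", n_boot=40, seed=5, preference_deg=100.0)
        assert r.ci95 is not None
        assert r.ci95[0] == r.ci95[1] == pytest.approx(r.mean_shift)

    def test_fast_bootstrap_matches_general_pipeline(self):
        """The numpy bootstrap path equals the pandas pipeline on the same
        resamples (checked distributionally on noiseless data)."""
        tr = _noiseless_neuron(c=0.0)
        rng = np.random.default_rng(0)
        boots = bootstrap_shifts(tr, "SP", 20, rng, preference_deg=100.0)
        point = estimate_shift(tr, 0, "SP", n_boot=0, preference_deg=100.0)
        assert np.allclose(boots, point.mean_shift)

    def test_missing_neuron_rejected(self):
        tr = _noiseless_neuron(c=0.0)
        with pytest.raises(ValueError):
            estimate_shift(tr, 99, "SP")


def test_population_table_schema():
    from headingshift.shift_analysis import estimate_shifts_population

    frames = [
        simulate_trials(
            NeuronSpec(base=VonMisesParams(A=60.0, phi_deg=phi, k=3.0),
                       c_rp=0.0, c_sp=0.0),
            reps=5, seed=i, neuron_id=i,
        )
        for i, phi in enumerate([60.0, 250.0])
    ]
    table = estimate_shifts_population(pd.concat(frames), n_boot=30, seed=1)
    assert set(table.columns) >= {
        "neuron_id", "condition", "mean_shift_deg", "ci_lo", "ci_hi",
        "n_gated_halves",
    }
    assert len(table) == 4  # 2 neurons × RP/SP
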