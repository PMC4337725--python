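import numpy as np
import pytest

from headingshift.synthetic_neurons import (
    NeuronSpec,
    VonMisesParams,
    WarpedVonMises,
    calibrate_gamma,
    calibrate_sigma,
    evaluate,
    expected_bandwidth_sign,
    expected_peak_shift_sign,
    eye_heading_deg,
    is_lateral_preference,
    make_rotation_added_curve,
    numeric_fwhh_deg,
    peak_heading_deg,
    simulate_rotation_responses,
    simulate_trials,
    simulate_validation_suite,
    temporal_rate,
    vm,
    vm_fwhh_deg,
    vm_skew,
    vm_width,
)

GRID = np.arange(0.0, 360.0, 1.0)


class TestVonMises:
    def test_peak_value_is_amplitude(self):
        p = VonMisesParams(A=37.0, phi_deg=123.0, k=2.0)
        assert vm(123.0, p) == pytest.approx(37.0)

    def test_antipode_value_k1(self):
        p = VonMisesParams(A=10.0, phi_deg=90.0, k=1.0)
        assert vm(270.0, p) == pytest.approx(10.0 * np.exp(-2.0))

    def test_fwhh_closed_form_vs_numeric(self):
        """Closed-form widths match the numeric oracle (k = 2).

        Half of the peak amplitude gives 2·acos(1 − ln2/k) ≈ 98.5°; the
        (min+max)/2 crossing used for measured curves solves
        cosΔ = 1 + ln((1+e^{−2k})/2)/k.
        """
        k = 2.0
        p = VonMisesParams(A=50.0, phi_deg=90.0, k=k)
        assert vm_fwhh_deg(k) == pytest.approx(98.5, abs=0.2)
        half = (1.0 + np.exp(-2 * k)) / 2.0
        closed_minmax = 2.0 * np.degrees(np.arccos(1.0 + np.log(half) / k))
        assert numeric_fwhh_deg(p) == pytest.approx(closed_minmax, abs=0.05)

    def test_values_in_unit_range(self):
        p = VonMisesParams(A=60.0, phi_deg=0.0, k=3.0)
        v = vm(GRID, p)
        assert np.all(v > 0) and v.max() == pytest.approx(60.0)


class TestWidthDeformation:
    def test_sigma_zero_reduces_to_plain(self):
        p = VonMisesParams(A=60.0, phi_deg=45.0, k=2.0, sigma=0.0)
        assert np.max(np.abs(vm_width(GRID, p) - vm(GRID, p))) == 0.0

    @pytest.mark.parametrize("sigma", [-0.5, 0.3, 0.8])
    def test_peak_stays_at_preference(self, sigma):
        p = VonMisesParams(A=60.0, phi_deg=100.0, k=2.0, sigma=sigma)
        assert peak_heading_deg(p) == pytest.approx(100.0, abs=0.05)

    def test_sigma_sign_controls_width(self):
        base = VonMisesParams(A=60.0, phi_deg=0.0, k=2.0)
        w0 = numeric_fwhh_deg(base)
        narrower = numeric_fwhh_deg(VonMisesParams(60.0, 0.0, 2.0, sigma=0.5))
        wider = numeric_fwhh_deg(VonMisesParams(60.0, 0.0, 2.0, sigma=-0.5))
        assert narrower < w0 < wider

    def test_calibration_hits_target_width(self):
        base = VonMisesParams(A=60.0, phi_deg=180.0, k=2.0)
        s = calibrate_sigma(base, 40.0)
        got = numeric_fwhh_deg(VonMisesParams(60.0, 180.0, 2.0, sigma=s))
        assert got == pytest.approx(numeric_fwhh_deg(base) + 40.0, abs=0.1)


class TestSkewDeformation:
    def test_gamma_zero_reduces_to_plain(self):
        p = VonMisesParams(A=60.0, phi_deg=45.0, k=2.0, gamma=0.0)
        assert np.max(np.abs(vm_skew(GRID, p) - vm(GRID, p))) == 0.0

    def test_peak_displacement_sign_flips_with_gamma(self):
        base = VonMisesParams(A=60.0, phi_deg=100.0, k=2.0)
        d_pos = peak_heading_deg(VonMisesParams(60, 100, 2.0, gamma=0.3)) - 100.0
        d_neg = peak_heading_deg(VonMisesParams(60, 100, 2.0, gamma=-0.3)) - 100.0
        assert d_pos * d_neg < 0

    def test_bisection_calibration_20deg_at_k2(self):
        base = VonMisesParams(A=60.0, phi_deg=100.0, k=2.0)
        g = calibrate_gamma(base, 20.0)
        p = VonMisesParams(60.0, 100.0, 2.0, gamma=g)
        assert peak_heading_deg(p) == pytest.approx(120.0, abs=0.05)

    def test_trough_moves_opposite_to_peak(self):
        base = VonMisesParams(A=60.0, phi_deg=100.0, k=2.0)
        g = calibrate_gamma(base, 20.0)
        p = VonMisesParams(60.0, 100.0, 2.0, gamma=g)
        fine = np.arange(0.0, 360.0, 0.01)
        trough = fine[np.argmin(evaluate(fine, p))]
        assert trough < 280.0  # base trough at 280°, displaced backward


class TestRotationAddedCurves:
    def test_full_compensation_returns_base(self):
        base = VonMisesParams(A=60.0, phi_deg=100.0, k=3.0)
        out = make_rotation_added_curve(base, "right", "cloud", c=1.0)
        assert isinstance(out, VonMisesParams)
        assert out.phi_deg == base.phi_deg and out.sigma == 0.0 and out.gamma == 0.0

    @pytest.mark.parametrize(
        "phi,direction,sign",
        [
            (100.0, "right", +1), (100.0, "left", -1),  # forward-preferring
            (280.0, "right", -1), (280.0, "left", +1),  # backward-preferring
        ],
    )
    def test_peak_shift_direction_table(self, phi, direction, sign):
        assert expected_peak_shift_sign(phi, direction) == sign
        base = VonMisesParams(A=60.0, phi_deg=phi, k=3.0)
        out = make_rotation_added_curve(base, direction, "cloud", c=0.0)
        disp = (peak_heading_deg(out) - phi + 180.0) % 360.0 - 180.0
        assert disp == pytest.approx(sign * 20.0, abs=0.2)

    @pytest.mark.parametrize(
        "phi,direction,sign",
        [
            (0.0, "right", +1), (0.0, "left", -1),  # 0°-preferring: right widens
            (180.0, "right", -1), (180.0, "left", +1),  # 180°: right narrows
        ],
    )
    def test_bandwidth_direction_table(self, phi, direction, sign):
        assert expected_bandwidth_sign(phi, direction) == sign
        base = VonMisesParams(A=60.0, phi_deg=phi, k=3.0)
        out = make_rotation_added_curve(base, direction, "cloud", c=0.0)
        dw = numeric_fwhh_deg(out) - numeric_fwhh_deg(base)
        assert dw == pytest.approx(sign * 40.0, abs=0.5)

    def test_geometric_mode_warps_halves_oppositely(self):
        base = VonMisesParams(A=60.0, phi_deg=100.0, k=3.0)
        out = make_rotation_added_curve(base, "right", "cloud", c=0.0, mode="geometric")
        assert isinstance(out, WarpedVonMises)
        disp = (peak_heading_deg(out) - 100.0 + 180.0) % 360.0 - 180.0
        assert disp == pytest.approx(20.0, abs=0.5)

    def test_overcompensation_flips_direction(self):
        base = VonMisesParams(A=60.0, phi_deg=100.0, k=3.0)
        out = make_rotation_added_curve(base, "right", "cloud", c=1.2)
        disp = (peak_heading_deg(out) - 100.0 + 180.0) % 360.0 - 180.0
        assert disp == pytest.approx(-4.0, abs=0.2)

    def test_lateral_band_membership(self):
        assert is_lateral_preference(0.0)
        assert is_lateral_preference(355.0)
        assert is_lateral_preference(175.0)
        assert not is_lateral_preference(90.0)
        assert not is_lateral_preference(20.0)  # band edge treated as fore/aft


class TestTrialSimulation:
    def test_same_seed_same_trials(self):
        n = NeuronSpec()
        a = simulate_trials(n, reps=5, seed=11)
        b = simulate_trials(n, reps=5, seed=11)
        assert a.equals(b)

    def test_zero_rate_neuron_gives_zero_trials(self):
        n = NeuronSpec(
            base=VonMisesParams(A=1e-9, phi_deg=90.0, k=3.0),
            baseline_sps=0.0,
            offset_range=(0.0, 0.0),
        )
        tr = simulate_trials(n, reps=5, seed=1)
        assert np.all(tr["rate_sps"].to_numpy() == 0.0)

    def test_trial_means_converge_to_generative_curve(self):
        """Law of large numbers: many-rep means approach the noiseless rates."""
        n = NeuronSpec(baseline_sps=5.0, offset_range=(0.0, 0.0), gain_range=(1.0, 1.0))
        tr = simulate_trials(n, reps=400, seed=3)
        sub = tr[tr["condition"] == "translation_only"]
        means = sub.groupby("heading_deg")["rate_sps"].mean()
        expected = 5.0 + vm(means.index.to_numpy(), n.base)
        se = np.sqrt(expected / 0.75 / 400)
        assert np.all(np.abs(means.to_numpy() - expected) < 3 * se + 1e-9)

    def test_rates_non_negative(self):
        n = NeuronSpec()
        tr = simulate_trials(n, reps=5, seed=5, include_controls=True)
        assert (tr["rate_sps"] >= 0).all()

    def test_schema(self):
        tr = simulate_trials(NeuronSpec(), reps=4, seed=0, include_controls=True)
        assert list(tr.columns) == [
            "neuron_id", "condition", "heading_deg", "repetition", "rate_sps",
        ]
        assert set(tr["condition"]) >= {
            "translation_only", "RP_left", "RP_right", "SP_left", "SP_right",
            "pursuit_dark_left", "sim_rotation_right", "blank", "static_fix",
        }
        reps = tr.groupby(["condition", "heading_deg"], dropna=False).size()
        assert (reps == 4).all()


class TestValidationSuite:
    def test_regeneration_is_deterministic(self):
        a, ta = simulate_validation_suite(n_sets=2, seed=5)
        b, tb = simulate_validation_suite(n_sets=2, seed=5)
        assert a.equals(b) and ta.equals(tb)

    def test_ground_truth_is_20_everywhere(self, validation_suite):
        _, truth = validation_suite
        assert (truth["true_shift_deg"] == 20.0).all()
        assert truth["preference_deg"].nunique() == 18

    def test_noiseless_unit_nuisance_recovers_20_exactly_on_skew_neurons(self):
        from headingshift.shift_analysis import estimate_shift

        trials, truth = simulate_validation_suite(
            n_sets=1, seed=0, noise=False, gain_range=(1.0, 1.0),
            offset_range=(0.0, 0.0), preferences_deg=np.array([60.0, 100.0, 240.0]),
        )
        for nid, pref in zip(truth["neuron_id"], truth["preference_deg"]):
            r = estimate_shift(trials, nid, "SP", n_boot=0, preference_deg=pref)
            assert r.mean_shift == pytest.approx(20.0, abs=1.0)


class TestTemporal:
    def test_head_centered_drive_is_flat(self):
        t = np.linspace(375.0, 1125.0, 751)
        n = NeuronSpec(frame_weight=0.0)
        r = temporal_rate(n, "SP", "right", 60.0, t)
        assert np.ptp(r) == pytest.approx(0.0, abs=1e-12)

    def test_translation_drive_flat_for_any_weight(self):
        t = np.linspace(0.0, 1499.0, 1500)
        for lam in (0.0, 0.5, 1.0):
            n = NeuronSpec(frame_weight=lam)
            r = temporal_rate(n, "translation", None, 60.0, t)
            assert np.ptp(r) == pytest.approx(0.0, abs=1e-12)

    def test_eye_centered_slope_matches_analytic_gradient(self):
        """Noise-free λ=1 drive slope equals dF/dθ · ω on the plateau."""
        from scipy.stats import linregress

        n = NeuronSpec(frame_weight=1.0, baseline_sps=0.0)
        # rising flank of the k=3 curve (peak 90°): heading 45°
        t = np.linspace(400.0, 1100.0, 701)
        r = temporal_rate(n, "SP", "right", 45.0, t)
        fit = linregress(t / 1000.0, r)
        h_mid = eye_heading_deg(45.0, "right", np.array([750.0]), 1.0)[0]
        d = np.radians(h_mid - 90.0)
        grad = -n.base.A * n.base.k * np.sin(d) * np.exp(
            n.base.k * (np.cos(d) - 1.0)
        ) * np.pi / 180.0  # per degree
        assert fit.slope == pytest.approx(grad * 17.0, rel=0.01)

    def test_eye_heading_sweep_is_centered(self):
        t = np.array([0.0, 750.0, 1500.0])
        h = eye_heading_deg(90.0, "right", t, 1.0)
        assert h[1] == pytest.approx(90.0)
        assert h[0] == pytest.approx(90.0 - 9.5625)
        assert h[2] == pytest.approx(90.0 + 9.5625)


class TestRotationResponses:
    def test_same_seed_reproducible(self):
        pop = [NeuronSpec() for _ in range(5)]
        a = simulate_rotation_responses(pop, rho=0.5, seed=2)
        b = simulate_rotation_responses(pop, rho=0.5, seed=2)
        assert a.equals(b)

    def test_rho_one_gives_identical_latents(self):
        """With ρ = 1 the visual and non-visual drives coincide exactly."""
        pop = [NeuronSpec(baseline_sps=50.0) for _ in range(40)]
        df = simulate_rotation_responses(pop, rho=1.0, seed=3, reps=200)
        per = df.groupby(["neuron_id", "condition"])["rate_sps"].mean().unstack()
        for d in ("left", "right"):
            diff = per[f"pursuit_dark_{d}"] - per[f"sim_rotation_{d}"]
            assert np.abs(diff).mean() < 2.0  # only Poisson noise separates them

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            simulate_rotation_responses([NeuronSpec()], rho=1.5, seed=0)
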