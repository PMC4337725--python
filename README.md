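# headingshift

Tools for studying **rotation-invariant heading coding**: the optic-flow
geometry of combined self-translation and eye rotation, synthetic
populations of heading-tuned neurons with controlled rotation
compensation, and the statistical estimators that measure how much a
neuron's heading tuning is transformed when rotation is added to
translation.

The package is aimed at sensory/systems neuroscientists and modelers who
work with heading tuning under pursuit eye movements — for planning
experiments, validating analysis pipelines against synthetic ground truth,
or exploring the visual geometry itself.

## The problem

Forward translation produces an expanding retinal flow field whose
singularity (the focus of expansion, FOE) indicates heading. Eye rotation
adds a depth-independent flow component that displaces the FOE by a
depth-*dependent* amount — at 24 cm/s translation with 17°/s yaw, a plane
at 25 cm shows a ≈20° FOE shift, and beyond T/(2ω) ≈ 40 cm the FOE
vanishes entirely. A neuron that encodes the resultant flow rather than
heading therefore shows systematic tuning transformations when rotation is
added: skewed curves (peak and trough displaced oppositely) for fore/aft
heading preferences, bandwidth changes for lateral preferences.

## The core statistic

Heading tuning is modeled as a von Mises curve over azimuth θ,

    VM(θ) = A·exp{k·[cos(θ − φ) − 1]},

optionally deformed in width (σ) or skew (γ). The **partial-shift
estimator** quantifies the rotation-induced transformation in three steps:
(1) match the rotation-added curve's trough and dynamic range to the
pure-translation curve; (2) split into forward (0–180°) and backward
(180–360°) heading halves, gate each by a one-way ANOVA (p ≤ 0.05), and
interpolate both curves to 1° on the circle; (3) circularly shift the
translation curve in 1° steps to minimize the squared error against each
gated half. The four partial shifts (2 halves × 2 rotation directions) are
sign-aligned so positive = under-compensation and averaged; 95% CIs come
from a 300-resample stratified percentile bootstrap. A legacy
cross-correlation estimator (±32° window, 8° sampling) is included as the
baseline it replaces, together with population metrics (FWHH bandwidth
tests, compensation classification, rotation-response correlations) and a
temporal-slope analysis that separates *reference frame* (eye- vs
head-centered, weight λ) from *rotation invariance* (compensation c).

## Worked example

```python
from headingshift import (SelfMotionState, find_foe, NeuronSpec,
                          VonMisesParams, simulate_trials, estimate_shift)

# 1. flow geometry: depth-dependent FOE shifts under 24 cm/s + 17°/s yaw
motion = SelfMotionState(translation_speed_cm_s=24,
                         heading_azimuth_deg=90, yaw_rate_deg_s=17)
for depth in (25, 35, 45):
    foe = find_foe(motion, depth_plane_cm=depth)
    print(f"FOE at {depth} cm:",
          f"{foe.azimuth_deg:.1f} deg" if foe.defined else "undefined")

# 2. a neuron that compensates more during real than simulated pursuit
neuron = NeuronSpec(base=VonMisesParams(A=60, phi_deg=100, k=3),
                    c_rp=0.6, c_sp=0.2)
trials = simulate_trials(neuron, reps=5, seed=1)
for cond in ("RP", "SP"):
    r = estimate_shift(trials, 0, cond, n_boot=300, seed=2)
    print(f"{cond}: shift = {r.mean_shift:.1f} deg, "
          f"95% CI = ({r.ci95[0]:.1f}, {r.ci95[1]:.1f})")
```

prints

```
FOE at 25 cm: 19.8 deg
FOE at 35 cm: 33.0 deg
FOE at 45 cm: undefined
RP: shift = 5.0 deg, 95% CI = (1.3, 11.7)
SP: shift = 15.5 deg, 95% CI = (-2.6, 22.0)
```

The FOE shift grows with plane depth until the flow is rotation-dominated
and the singularity disappears. The simulated neuron compensates 60% for
rotation during real pursuit and 20% during simulated pursuit, so its
measured shifts sit near (1−c)·20°: ≈5° (RP) versus ≈16° (SP) — the
signature of extra-retinal cues improving rotation tolerance, with the
bootstrap CIs showing the per-neuron uncertainty at five repetitions.

A full pipeline (simulate → shifts → benchmarks → reports) is available
from the shell:

```bash
headingshift run-all --seed 7 --out runs/demo
```

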