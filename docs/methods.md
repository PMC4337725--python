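# Methods

This note documents the models, estimators and numerical choices behind
`headingshift`, in the spirit of a methods section: what is computed, under
which assumptions, and where the genuinely open design choices were made.

## 1. Optic-flow geometry

Coordinates are right-handed and eye-centered: +X rightward, +Y upward, +Z
into the scene. Heading azimuth lies in the horizontal plane with 0° =
rightward, 90° = straight ahead, 180° = leftward, 270° = backward; positive
yaw means a rightward eye rotation. A scene point P = (X, Y, Z) projects
onto a flat screen at viewing distance D (default 30 cm, 60 × 60 cm, i.e. a
90° × 90° field) as (x, y) = (D·X/Z, D·Y/Z). With observer translation
**T** and yaw ω the point moves at −**T** − ω×P relative to the eye, and
differentiating the projection gives

    vx = (−D·Tx + x·Tz)/Z − ω·(D + x²/D)
    vy = (−D·Ty + y·Tz)/Z − ω·(x·y/D)          (ω in rad/s)

The grouping is deliberate: the translational part carries the 1/Z factor
(motion parallax), while the rotational part depends only on the screen
position — the code computes it from screen coordinates so that the
depth-invariance of rotational flow holds *exactly*, not just to rounding.
The rotational term itself splits into a uniform (laminar) component −ωD
and position-dependent terms −ωx²/D, −ωxy/D: the dynamic-perspective
distortion, zero at the screen center and growing quadratically with
eccentricity.

**Focus of expansion.** On the horizontal meridian the horizontal velocity
is quadratic in x: (ω/D)x² − (Tz/Z)x + D(Tx/Z + ω) = 0. When two real
roots exist the one continuously connected to the pure-translation FOE
(x = D·Tx/Tz) is reported; a negative discriminant means rotation dominates
and the FOE is undefined. For forward heading the critical depth is
T/(2ω) ≈ 40.4 cm at 24 cm/s and 17°/s.

**Angular reporting convention.** FOE azimuths are reported in
*screen-linear degrees*, (x/D)·180/π — the screen offset at the small-angle
scale of the display — with the true visual angle atan(x/D) kept as a
secondary field. The screen-linear convention reproduces both printed
anchors of the display geometry this package models (≈20° at the 25 cm
plane — the value the acceptance script reports — and 33° at 35 cm),
whereas the atan convention gives 19.1°/30.0°. The two agree to first
order and differ only by the tangent's curvature at large offsets.

**Motion parallax and timecourse.** The parallax field is the pointwise
difference between two depth slices; because the rotational term is
depth-free it cancels exactly and the difference equals
(1/Z_near − 1/Z_far) times the unit-depth translational field, with its
singularity at the true heading for any yaw rate. The approaching-wall
timecourse evaluates the FOE at each 60 Hz frame of the 375–1125 ms
plateau while the plane distance follows 45 cm minus the integrated
trapezoid, reporting the time-average of defined shifts and the undefined
fraction.

## 2. Stimulus protocol

Trials last 1500 ms with trapezoidal speed profiles: linear ramps over
0–375 ms and 1125–1500 ms and a constant plateau (24 cm/s translation,
17°/s rotation) over the middle 750 ms — the analysis window for all rate
statistics. The integral of the trapezoid has the closed form
peak·(plateau + ramp); at 24 cm/s that is 27 cm of simulated travel, which
takes the fronto-parallel wall from 45 cm to 18 cm. One block crosses 8
headings (45° steps) with five main condition types — pure translation,
real pursuit left/right (RP), visually simulated pursuit left/right (SP) —
plus eight controls (pursuit in darkness L/R, pursuit over static dots
L/R, simulated rotation L/R, blank screen, static fixation): 48 unique
conditions. Pursuit targets start 9.5° off-center and sweep 19.125° with
the rotation trapezoid. All schedules are discretized at the 60 Hz display
rate.

## 3. Synthetic neurons

Heading tuning is the von Mises family

    VM(θ)       = A·exp(k·[cos(θ−φ) − 1])
    VM_width(θ) = A·exp(k·[cos(θ−φ+σ·sin(θ−φ)) − 1])
    VM_skew(θ)  = A·exp(k·[cos(θ−φ+γ·cos(θ−φ)) − 1])

with peak rate A, preferred heading φ and concentration k; σ = γ = 0
recovers the plain curve. σ deforms the half-height slope symmetrically
(σ > 0 narrows); γ displaces peak and trough in opposite directions
(≈ ∓γ radians to first order) while skewing the flanks. The skew phase is
written γ·cosΔ rather than γ·(cosΔ−1): with the latter the curve's value
at Δ = 0 is always the global maximum, so *no* γ could displace the peak,
contradicting the deformation's purpose; the cosΔ form is the member of
the family whose peak and trough move oppositely — the geometric signature
of uncompensated rotation for fore/aft preferences. Both deformations are
calibrated numerically (Brent bisection against a 0.01° argmax / FWHH
oracle).

**What rotation does to tuning.** An uncompensated neuron responds to the
resultant flow, whose apparent heading is displaced oppositely for forward
(0–180°) and backward (180–360°) headings. Two constructions are
implemented:

- `peak_shift` (default; the construction under which the estimator's
  recovery was validated): fore/aft-preferring neurons get a rigid
  displacement of the preferred direction by ±(1−c)·20° (cloud stimulus;
  37° for the approaching plane); lateral-preferring neurons (φ strictly
  within 20° of 0° or 180°) get a σ bandwidth change of ±(1−c)·40° FWHH.
- `geometric`: a heading-half-referenced warp r(θ) = base(θ − d·u(θ)),
  u(θ) = tanh(β sinθ)/tanh(β), β = 4, displacing the forward half by +d
  and the backward half by −d with a smooth transition at 0°/180°.

Both obey the same direction table: rightward rotation shifts
forward-preferring peaks toward larger azimuths and backward-preferring
peaks toward smaller ones, widens 0°-preferring tuning and narrows
180°-preferring tuning; leftward rotation mirrors everything. The
compensation parameter c scales the deformation: c = 1 is fully
rotation-invariant, c = 0 fully uncompensated, c > 1 over-compensates
(deformation flips direction).

**Trial noise.** Expected rates per condition are gain·curve(θ) + offset +
baseline, with gain ~ U(0.66, 1.33) and offset ~ U(0, 40 sp/s) drawn per
rotation-added condition. Poisson noise is applied to spike *counts* over
the 750 ms plateau (not to rates), reproducing rate-dependent variance;
negative expected rates are clipped at zero with a warning.

**Validation suite.** 10 replicate sets × 18 preferences (20° spacing),
k = 3 (FWHH ≈ 81°, within the range of parietal heading-tuning
bandwidths), A = 60 sp/s, 5 repetitions, 45° sampling, c = 0 — every
neuron carries a constructed 20° transformation. k was chosen so the
trough half of a fore/aft-preferring curve carries essentially no tuning
signal of its own; with much broader tuning the flanks reach the
forward/backward boundary and the half-based estimator has no clean
displacement to read (see §4).

**Time-resolved responses.** The instantaneous drive is the condition's
tuning curve evaluated at the heading in eye coordinates, which drifts
with the integrated rotation scaled by the reference-frame weight λ
(λ = 1 eye-centered: full drift; λ = 0 head-centered: constant), centered
so the sweep is symmetric about mid-trial. Spikes are inhomogeneous
Poisson at 1 ms resolution. Rotation-control responses (pursuit in
darkness vs simulated rotation) draw latent non-visual/visual amplitude
pairs from a bivariate normal with population correlation ρ.

## 4. The partial-shift estimator

Three steps, per neuron and rotation condition:

1. **Normalize** — the rotation-added curve's trough and dynamic range are
   matched to the pure-translation curve by a vertical shift and scale
   (removing gain fields and additive offsets exactly).
2. **Gate and interpolate** — each half (forward 0–180°, backward
   180–360°) must be significantly tuned by a one-way ANOVA across its
   headings (p ≤ 0.05); curves are linearly interpolated on the circle to
   1°.
3. **Shift search** — the translation curve is circularly shifted in 1°
   steps over ±90° to minimize the SSE against each gated half over that
   half's 181-point support; ties break toward the smaller |lag|.

The four partial shifts (2 halves × 2 rotation directions) are
sign-aligned so that positive = under-compensation, then averaged.
Alignment is preference-aware: lateral-preferring neurons use the per-half
table (forward/right +, forward/left −, backward/right −, backward/left
+, i.e. the bandwidth-change directions), while fore/aft-preferring
neurons align both halves by the preference's expected displacement sign.
An `absolute` averaging mode (mean |shift|) is provided for sensitivity
analyses. The preferred heading used by the alignment is the argmax of the
interpolated translation curve, or a caller-supplied value when ground
truth is known (simulations).

Two deliberate refinements, both forced by measurable failure modes:

- **The ANOVA gate uses each half's interior headings only** (the shared
  boundary samples 0°/180° stay in the SSE support). Including boundaries
  in the gate lets the tuned half's flank "gate in" the flat trough half,
  which then contributes near-arbitrary lags: on the validation suite this
  collapses the grand mean from ≈20° to ≈5°.
- **Bounds of the estimator**: the trough half of a fore/aft neuron has
  its only signal at the (shared, deformation-anchored) boundary samples,
  so no smooth single-valued deformation lets it read the opposite-signed
  displacement; recovery therefore rests on the peak-bearing half, and
  interior gating keeps the trough half out unless it is genuinely tuned.

**Bootstrap.** 300 replicates resample trials with replacement within each
heading × condition cell (stratified, preserving the design balance); the
full pipeline runs per replicate and the 95% CI is the 2.5/97.5 percentile
of replicate means; replicates with no gated half are dropped and counted.
Measured coverage of the constructed 20° shift at the study's trial counts
(5 repetitions) is ≈95%. A vectorized numpy path (identical output,
verified against the general pipeline) handles the standard 8 × 45° grid.

**Compensation classes** from the CI: `invariant` (CI ∋ 0), `over` (CI
entirely < 0), `none` (cloud rule: CI entirely above the 20° reference;
plane rule: CI containing or exceeding 37°), else `partial`.

## 5. The legacy cross-correlation baseline

Curves sampled only at ±32° around straight ahead in 8° steps (9 points)
are smoothed with a 3-point moving average (2-point at the ends — the
window is not circular), interpolated with a natural cubic spline to 1°,
and the lag in ±30° maximizing the Pearson correlation is reported; lags
overlapping fewer than half the samples are excluded. Correlation is
affine-invariant, so gain/offset nuisance is ignored by construction. The
benchmark sweeps preferences 0–180° (10 sets, both rotation directions,
leftward lags negated): near 90° the mean lag is ≈20°; at lateral
preferences the in-window curve is monotonic, the correlation function
flat, and the lag biased and high-variance — the documented failure that
motivates the partial-shift estimator.

## 6. Population metrics

FWHH is the longest contiguous circular arc at or above (min+max)/2 with
linearly interpolated crossings (robust to noise-induced secondary bumps;
note this (min+max)/2 reference is slightly narrower than the half-of-A
closed form 2·acos(1−ln2/k) because the von Mises trough is nonzero).
Bandwidth changes of lateral-preferring groups are compared with Wilcoxon
rank-sum tests per rotation direction. Population shift summaries report
RP/SP medians, the paired signed-rank test between them, signed-rank tests
against 0 and against the reference shift, and the RP−SP difference
distribution. Rotation-control analysis reports per-neuron
baseline-subtracted responses with significance flags (Welch t-test by
default, rank-sum optionally), leftward−rightward differences, and
Spearman correlations between pursuit-in-darkness and simulated-rotation
responses (per direction and for the L−R differences).

## 7. Temporal reference-frame analysis

Per neuron × condition, the heading with the largest positive circular
central-difference gradient on the 45° grid is selected; curves whose
response there is not significantly different (t-test, p ≤ 0.05) from both
immediate neighbors are excluded (the true steepest point may hide a peak
or trough between samples). Spike trains at the selected heading are
binned at 1 ms, convolved with a 25 ms Gaussian kernel (edge-corrected so
the trace integrates to the spike count), averaged over repetitions,
normalized by the neuron's pure-translation dynamic range, averaged across
neurons, and regressed on time over the 375–1125 ms plateau.

The eye-centered prediction is the population-mean normalized gradient
times the rotation speed, signed by direction. Two numerical choices
deviate from the naive recipe, both after quantifying the alternative:

- The slope CI comes from the across-neuron dispersion of per-trace
  slopes (1.96·SEM), not the mean-trace regression SE — smoothed samples
  are serially correlated and the OLS SE is ~5× too narrow, flagging
  honestly flat translation traces as "sloped".
- The frame-weight estimate λ̂ divides measured slopes by a prediction
  based on the *analytic derivative of a von Mises fit* to the 8 sampled
  means at the selected heading. The 45° central difference averages the
  derivative over a 90° window and under-reads it by ~1.4× at k = 3,
  inflating λ̂ = 1 populations to ≈1.5; the fit-based prediction recovers
  planted λ within ±0.15 at 72 neurons and 5 repetitions (the
  central-difference prediction is still reported alongside for
  comparability).

## 8. What the synthetic data do and do not show

The generator emulates the *statistical structure* of the recordings —
trial counts, Poisson variability, gain fields, response offsets, the
geometry-dictated tuning transformations, graded compensation and
reference-frame weighting — but not receptive-field structure, speed or
disparity tuning, adaptation, or correlated noise across neurons. Passing
tests therefore demonstrate that the estimators recover known parameters
under realistic noise and nuisance at the recorded sample sizes; they do
not certify behavior on real neurons whose deformations depart from the
von Mises family, nor do they reproduce the original population's specific
medians and correlations, which depend on data that are not public.

## 9. Problem sizes and reproducibility

Default problem sizes: validation suite 10 × 18 neurons; bootstrap 300
resamples; benchmark 10 sets × 10 preferences; population studies 72
neurons × 5 repetitions (the recorded cohort's size). One master seed
expands into per-stage seeds via SeedSequence over a CRC32 of the stage
name; every simulation is reproducible from (config, seed), and the CLI
writes a manifest with the seed and config hash. All tabular outputs are
plain CSV with documented headers.
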