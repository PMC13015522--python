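# Methods

This note documents the models, procedures and numerical choices behind
`tiltpost`, and what the synthetic-data generator does and does not
emulate.

## Perturbation design

A rotational support-surface perturbation is parameterized by peak angular
acceleration A (deg/s²), peak angular velocity V (deg/s) and total angular
displacement D (deg). The platform command is a trapezoidal velocity
profile produced by a piecewise-constant acceleration signal: +A for
d₁ = V/A, zero for d₂ = (D − V²/A)/V, and −A for d₁. The deceleration
block mirrors the acceleration block exactly (equal magnitude and
duration). Feasibility requires V²/A ≤ D; equality gives the triangular
(zero-plateau) boundary case.

The profile is constructed in continuous time with exact block durations,
integrated analytically (velocity piecewise linear, position piecewise
quadratic) and then sampled on the 100 samples/s platform command grid,
with the exact motion end time appended when it falls between grid
points. This preserves the total displacement to machine precision even
when d₁ or d₂ is not a grid multiple (e.g. V = 60, A = 500 gives
d₂ ≈ 0.0467 s). A `quantize_to_grid` option instead rounds the block
durations to the command grid, emulating a discrete-time platform command
stream, for fidelity studies; it is not used in the analysis pipeline.

The default protocol is a base profile (500 deg/s², 40 deg/s) shared
between a velocity set {20, 40, 60} deg/s at fixed acceleration and an
acceleration set {200, 500, 1000} deg/s² at fixed velocity, all with
D = 10 deg, delivered in four directions (forward/backward pitch,
leftward/rightward roll): 5 distinct profiles × 4 directions = 20
conditions. Sign convention: forward pitch and leftward roll are
positive; this mapping is centralized in `design.DIRECTION_SIGN` and all
downstream sign handling refers to it. No command smoothing is applied
(none is modeled for the physical platform).

## Dual-pendulum model

The body is reduced to a trunk–limb segment pivoting about the ankles
(mass m₁, COM distance l₁, inertia I₁) and a head segment articulated at
the neck (inertia I₂). With θ₁, θ₂ the segment angles from vertical and φ
the platform angle:

    τ₁ = −m₁ g l₁ θ₁ − k_platform (θ₁ − φ) − c_platform (θ̇₁ − φ̇)
    τ₂ = −k_neck (θ₂ − θ₁) − c_neck (θ̇₂ − θ̇₁)
    θ̈₁ = τ₁ / I₁,  θ̈₂ = τ₂ / I₂

The model is linear, small-angle, and one-way coupled: the neck torque
does not react back on the trunk, and the head segment carries no
gravitational or inertial-coupling term. The trunk gravity term is
restoring as written (a hanging-pendulum sign); an inverted pendulum
would carry +m₁ g l₁ θ₁ instead. We implement the restoring form as the
model's definition and expose `gravity_sign` (+1 restoring, −1 inverted)
for sensitivity analyses; the closed-form static equilibrium
θ₁* = k_platform φ₀ / (gravity_sign·m₁ g l₁ + k_platform), θ₂* = θ₁*
serves as an exact oracle in tests.

Integration uses adaptive RK45 (rtol 1e-8, atol 1e-10, max step 20 ms to
resolve acceleration-block edges) with output sampled on the 1000
samples/s analysis grid. The platform drive is built from the same
closed-form trapezoid as the waveform designer (deg → rad), so the model
sees exactly the designed command.

Parameter profiles are representative rhesus-scale values (≈7 kg trunk,
COM 0.18 m above the ankles) and are illustrative, not fitted to data.
Neck and body stiffness/damping have not been measured in monkeys, so two
extreme profiles bracket the qualitative regimes: `platform-following`
(stiff platform coupling, compliant neck — the trunk rides the platform)
and `stabilizing` (compliant platform coupling, stiff damped neck — head
motion is constrained in space).

## Kinetics and stance criteria

Center of pressure is computed from the four footplate load cells as
mass-normalized force differences:

    CoP_lat = ((F_FL + F_HL) − (F_FR + F_HR)) / m
    CoP_ap  = ((F_FL + F_FR) − (F_HL + F_HR)) / m

in N/kg. Plate geometry is never used, so these are force-difference
signals, not metric positions; all downstream metrics are labeled in
N/kg. The fore-aft expression is parenthesized as (front sum) − (hind
sum), mirroring the lateral equation's structure. Forces are not filtered
by default; a zero-phase 4th-order Butterworth low-pass is available.

Trial-start stance symmetry requires |front − hind| < 10 N,
|left − right| < 10 N, and head deviation < 10° on every axis, all strict
inequalities (10.0 exactly fails).

## Quality control

A trial is excluded when (i) video review flagged a stepping response
(consumed as a per-trial boolean; pose estimation is out of scope),
(ii) head angular velocity exceeds 20 deg/s on any axis during the 500 ms
pre-onset baseline, or (iii) head angular velocity exceeds 400 deg/s on
any axis anywhere from 500 ms before onset to 500 ms after motion offset.
Thresholds are strict "exceeds" applied per axis on the absolute value
(IMU channels are per-axis); a vector-norm mode is available by
configuration. A trial that cannot cover the baseline window is a
structural error, never a silent pass.

## Response metrics

Analysis windows are half-open — short latency [0, 100) ms and medium
latency [100, 200) ms after perturbation onset — so the boundary sample
is counted once. Onset latency is the first post-onset time at which
|signal − baseline mean| exceeds the RMS of the mean-subtracted 500 ms
baseline. Mean subtraction makes the threshold a true RMS *error*; an
epsilon floor (1e-9 channel units) guards the noiseless-baseline
degenerate case, and an optional N-consecutive-samples requirement
(default 1) suppresses single-sample glitches. A never-crossing trace
yields "not detected" (None), not an error.

Displacements are integrated over the platform-motion span [0, T] with T
the waveform's analytic motion end time: total angular displacement as
the trapezoidal integral of angular velocity, total linear displacement
as the double trapezoidal integral of linear acceleration, and CoP
trajectory length as the cumulated absolute CoP increment Σ|ΔCoP| — a
path length, consistent with sway-path measures (the literal signed
cumulative sum of CoP equals the plain sum of samples and is not a
length; the path-length reading is used throughout). Span masks carry a
half-sample tolerance so float rounding of T never drops the final grid
sample.

Condition averages are pointwise means with SEM = SD(ddof 1)/√n (0 when
n = 1) over trials synchronized at t = 0. Mirror-direction pooling
sign-flips the direction-odd channels of one side (for roll: roll/yaw
angular velocity, lateral acceleration, and CoP_lat via a left/right
plate swap; for pitch: pitch velocity, fore-aft acceleration, CoP_ap via
a front/hind swap) and concatenates the sets, e.g. 20 + 20 → 40 trials.

## Asymmetry index

Per-sample percentage error is unstable for zero-crossing oscillatory
responses, so the pairwise MAPE between two traces normalizes the mean
absolute difference at trace level: 100·mean|a−b| / mean|a| (reference =
first of the pair); a symmetric variant normalizes by the average of both
traces' levels and makes the index invariant to direction relabeling.
The within-direction distribution pools all same-direction pairs from
both directions; the across-direction distribution inverts one
direction's traces and takes all pairs of the pooled set regardless of
direction (the literal reading — same-direction pairs re-enter; a
cross-direction-only mode is provided). The index is
mean(across) − mean(within); significance uses a two-tailed Welch t-test
at α = 0.05 with the null of symmetry, and per-(animal, stimulus)
p-values are combined per axis with Fisher's method
(X = −2Σln pᵢ ~ χ²₂ₖ; pᵢ = 0 is rejected with guidance to clip).

Known limitation: the two MAPE distributions are not independent samples
— pairs share trials, and in the literal all-pairs reading the across
set contains the within set — so the t-test's nominal level is not
achieved in general. Empirically it is strongly conservative at the
generator's signal-to-noise ratio (essentially never rejecting under
symmetry) and anticonservative for noise-dominated traces. The index
itself is unbiased around 0 under symmetry, and the test retains power
against real gain asymmetries (a 1.5× one-sided gain is detected at
20 trials/side); p-values should nonetheless be read as heuristic.

## Condition-dependence statistics

Condition effects are tested with a two-way unbalanced ANOVA (factors
animal and condition, additive model, no interaction, Type-II sums of
squares) at p < 0.025 per factor — the threshold halves the familywise
0.05 across the two factors. Type II is the standard main-effects choice
without an interaction term and reduces to the classical decomposition on
balanced tables (verified to 1e-10 in tests). When the condition effect
is significant, the pooled dependence on the varied stimulus parameter is
quantified by OLS regression across all animals' trials with a two-sided
slope test at α = 0.05; the pipeline enforces this gating, while both
computations remain directly callable.

## Synthetic-data generator

The generator emulates the structure of the study's unreleased
recordings so every stage runs against injectable ground truth. Its
data-generating process encodes the headline dissociation: the
short-latency response amplitude is `short_accel_gain × peak_accel` and
the medium-latency amplitude is `medium_vel_gain × peak_vel`, each scaled
by a per-animal multiplicative offset (defaults 0.9/1.0/1.1, mean 1, so
pooled regressions are unbiased) and by a `direction_asymmetry` factor on
the negative direction. Response shapes are raised-cosine bumps —
smooth, parameter-free beyond onset and amplitude, and free of
discontinuities that would make onset-latency tests degenerate —
normalized to unit sampled mean over their analysis window, so at zero
noise the window means recover the injected amplitudes exactly.

Defaults mirror the study conditions: 20 trials per condition and
animal, 3 synthetic animals, the 20-condition protocol, 1000 samples/s,
≥500 ms pre-onset and post-offset padding, and ~10% contamination
(pre-onset drift peaking at 30 deg/s, a 450 deg/s post-offset head-shake
spike, or a stepping flag, drawn uniformly). CoP gains default to
2×10⁻³ N/kg per deg/s² (short) and 2×10⁻² N/kg per deg/s (medium),
giving response amplitudes of 0.4–2 N/kg across the stimulus range; head
channels scale the same structure by fixed per-channel factors (3 deg/s
and 0.25 m/s² per N/kg). Channel noise is white Gaussian (0.15 N/kg,
1 deg/s, 0.05 m/s²).

Head channels ride on a passive base: pitch trials use the
platform-following base (head velocity = platform command), roll trials
the dual-pendulum `stabilizing` profile, reflecting the axis-dependent
strategies the analysis is meant to resolve. Force traces are obtained by
inverting the CoP equations with the canonical equal split across the two
plates of each half, so `compute_cop` recovers the target CoP to machine
precision.

What the generator does not emulate: correlated (non-white) sensor
noise, trial-to-trial response-shape variability beyond scalar gains,
postural drift within trials, anticipatory adjustments, or
animal-specific strategy differences beyond scalar offsets. Passing
pipeline tests therefore demonstrate correctness of the computations
under the stated statistical structure, not robustness to every feature
of real recordings.

Randomness: one master seed; each trial draws from a counter-derived
`numpy` substream (`default_rng([seed, counter])`), so any subset of
trials is reproducible independently and full runs are byte-identical
under a fixed seed.

## Problem sizes used in tests

The test suite and acceptance checks run entirely on generated data: the
full default generator (1200 trials) for the dissociation-recovery
check, 500 seeded replicates of a two-condition roll set (10 trials/side)
for the symmetric-null calibration study, 1000 seeded traces for the
onset-latency oracle comparison, and reduced protocols (one axis, 2–3
trials per cell) for pipeline round trips. These sizes keep the suite
fast while leaving every statistical conclusion at its stated tolerance.
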