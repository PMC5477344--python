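# Methods

This note records the model, the numerical choices, and what the
simulator does and does not emulate. Angles are internal elbow angles in
degrees (extension increases the angle; protocol range 65–145°),
velocities in deg/s, torques in Nm; movements are in the horizontal plane
with the arm supported, so gravity never enters the dynamics.

## Trial structure and commanded trajectory

A trial is a flexion movement (145°→65°), a 1500 ms hold, an extension
movement back (65°→145°), and a 3000 ms hold; three trials per nominal
duration, slowest block (1500 ms) first, down to 600 ms. The commanded
trajectory is the half-cosine

θc(t) = θs + (θe − θs)(1 − cos(πt/T))/2, 0 ≤ t ≤ T,

the simplest sine-based profile with zero endpoint velocities; its peak
velocity is π·80/(2T) — 209.44 °/s at T = 600 ms. The source protocol
describes its command only as "based on a sine function", and its
published control mean peak velocity (306 °/s extension) exceeds what any
simple sine-lobe 80°/600 ms profile can produce, so the true commanded
shape is not recoverable; this package's defaults make no attempt to
reproduce those published magnitudes, and the packaged printed cutoffs in
`kaps.reference` are reference constants, not targets.

## Robot controller

During the movement window the motor torque is a PD loop with inertial
feedforward, saturated at the safety limit:

τ = clip( kp(θc − θ) + kd(θ̇c − θ̇) + Î·θ̈c, ±13.2 Nm ),

kp = 30 Nm/rad, kd = 2.5 Nm/(rad/s), Î = 0.12 kg·m² (a single fixed
inertia estimate; whether the original system personalised it is
unknown). After the nominal movement end the controller switches to a
soft proportional pull toward the target, 0.26 Nm/deg. The derivative
term is retained during the hold: with the proportional pull alone the
hold phase is an underdamped oscillator (ζ ≈ 0.1 for the default limb)
and any residual tracking error would ring past the target, which the
real machine does not do; with kd kept, ζ ≈ 0.9 and the limb settles
monotonically. If the target (within 1°; the source states no tolerance)
is not reached by the scheduled hold end, recording and control persist
until it is reached or until 7000 ms after movement onset, and the angle
reached then becomes the next movement's start angle.

## Limb model

One arm is a second-order rotational system,

I·θ̈ = τ_robot − b·θ̇ − g(t)·θ̇ − k_c·(θ − θ_c)₊,

with inertia I (default 0.12 kg·m²; ~0.14 male, ~0.105 female in the
cohort generator — forearm-plus-hand about the elbow), passive viscous
damping b (default 0.25 Nm/(rad/s), chosen so a healthy limb tracks the
600 ms command within 2°), a gated reflex gain g(t), and a one-sided
contracture spring of stiffness k_c engaging beyond extension angle θ_c.

The spastic reflex is deliberately the simplest mechanism that reproduces
the clinical catch-and-release phenomenology: g jumps from 0 to
`spastic_gain` once the excursion from the movement's start angle exceeds
`catch_onset_excursion` (the catch: an abrupt velocity drop at a
reproducible angle, time constant I/g ≈ 8 ms at the severe gain), resists
the remainder of the stretch (reduced peak velocity) and the hold-phase
pull (slow creep toward the target, time constant (g+b)/k_hold ≈ 1 s),
and decays exponentially with `release_time_constant` once |θ̇| falls
below 10 °/s (the release). No claim is made that this is the neural
mechanism; it is a generator of realistic kinematics.

Integration is fixed-step RK4 at the 1 kHz output rate (numba-compiled),
with the command evaluated analytically at the RK4 substages and the
reflex gain frozen within a step. |θ̇| > 100 rad/s raises an instability
error naming the offending parameters. Stability of the explicit scheme
bounds usable contracture stiffness at roughly 10³ Nm/deg — far beyond
any physiological value.

Measurement noise is additive Gaussian on the recorded angle only
(default SD 0.1°, encoder-grade); velocity is recorded from the true
state, as the real machine measures both.

## Cohort generator

Controls sample age uniform on 20–80 years, sex by a configurable
fraction, inertia per sex (SD 0.015 kg·m², shared by both arms — inter-arm
inertia asymmetry is physiologically negligible), and damping
N(0.25, 0.06) per subject with N(0, 0.02) between-arm jitter; an optional
linear age slope and sex offset on damping inject demographic effects
whose parameter-scale truth is obtained in tests by noise-free probe
simulations (Gauss–Hermite-averaged over the inertia distribution, since
peak velocity is nonlinear in the feedforward mismatch). Impaired
subjects apply a severity preset (mild/moderate/severe) to the test arm;
"severe" is reflex gain 15 Nm/(rad/s) engaging at 30° excursion plus a
2 Nm/deg contracture beyond 120°.

What the generator does **not** emulate, hence what passing tests do not
show about real data:

- Healthy between-arm asymmetry is far smaller than in real people: the
  fitted velocity-difference threshold comes out ~2 °/s versus the
  published 50.1 °/s, and control creep variance is noise-dominated
  (real controls show ~0.1–0.4° creep spread from viscoelastic tissue,
  which the healthy limb model lacks). Detection logic is exercised
  correctly, but fitted cutoff magnitudes are not comparable to
  published ones.
- Flexion and extension are mechanically symmetric per arm, so the two
  directions' parameters are strongly correlated — real spasticity is
  muscle-group specific.
- No trial-to-trial physiological variability (tone fluctuation,
  guarding), no EMG, no shoulder dynamics.

## Parameter extraction

Trials are filtered with a zero-phase (forward–backward) 2nd-order
Butterworth at 10 Hz; zero-phase is chosen so catch and velocity timing
are not lag-shifted (a real-time implementation would differ), the order
is unstated in the source. Windows come from the command clock, never
from data-driven onset detection. Final angle is the mean over the last
50 ms of the hold (noise-robust, versus the literal last sample). The
peak-velocity search runs from onset through the hold capped at the
7000 ms timeout, so movements completed late are captured. Per-subject
values are the mean of the three trials (configurable to median).
Trials whose target was never reached contribute their achieved
trajectories unchanged; there is no exclusion rule.

Catch detection compares each test-arm trial against the nominal
reference velocity — the onset-aligned mean across the reference arm's
trials (trial-to-trial pairing available as an option) — and reports the
median excursion at first threshold crossing across crossing trials,
absent if no trial crosses. The threshold is fitted as the control 99th
percentile of the per-subject *peak of the absolute between-arm velocity
difference trace*: detection scans that trace per sample, and the
difference-of-the-two-peaks (which is the reported between-arm
peak-velocity-difference parameter) is a strict lower bound on it, so
fitting the threshold on the latter would inflate the healthy
false-positive catch rate several-fold. The Weibull (exceedance-unbiased,
type 6) quantile definition is used for this extreme percentile: with
~100 controls, the default interpolated definition has an expected
exceedance of 2/(n+1) ≈ 2%, double the nominal 1% the threshold exists
to enforce. When no control data are supplied the published 50.1 °/s is
used and flagged `paper_default`.

## Normative model

Per parameter, in order, on the control table:

1. **Age regression** — OLS of value on age; all values are subsequently
   expressed at the mean control age (identity when age variance is
   zero, with a warning). Linear form assumed.
2. **Box-Cox** — ML lambda with the search bounded to [−5, 5] (outside
   this range the power transform over/underflows on near-constant
   samples whose profile likelihood is flat, without improving
   normality); shift 1 − min applied when values are not strictly
   positive. Normality verdict: Shapiro–Wilk p ≥ 0.01 on the transformed
   sample; parameters failing it are flagged nonparametric, keep raw
   percentile cutoffs, and carry no z-score.
3. **Outlier removal** — a control whose robust z (median/1.4826·MAD,
   epsilon-floored) exceeds 3.29 on *any* transformed parameter is
   excluded from all subsequent analyses (the original study removed 8
   of 96 controls without stating its rule; 3.29 ≈ two-sided 0.001 is
   the conventional choice and is configurable). Refuses if more than
   25% would be dropped.
4. **Sex / handedness effects** — two-sample t (normalizable) or
   Mann-Whitney (nonparametric) at α = 0.05; a sex effect triggers
   per-sex cutoffs when both strata hold ≥ 20 controls (else pooled with
   a warning); a handedness effect raises a warning only.
5. **Cutoffs** — one-tailed empirical percentiles (linear interpolation
   between order statistics) in transformed space, back-transformed for
   reporting; the impaired tail per parameter follows the parameter's
   semantics (slower, less extended, more creep, larger asymmetry). The
   back-transformed cutoff maps to exactly the cutoff percentile in
   transformed space by construction.
6. **Z-scores** — (transformed age-adjusted value − stratum mean)/SD,
   sign-oriented so positive points toward the impaired tail.

Classification is strict one-tailed (a value exactly at the cutoff is
normal — an arbitrary but fixed tie-break). A detected catch counts as a
failed slot in its own right, since the detection threshold is already
the control 99th percentile; failure counts run over 14 slots (7
parameters × 2 directions), with uncomputable parameters dropped from
the denominator and listed, and a count excluding the catch slots also
reported. Group summaries give percent impaired per parameter, cumulative
failure-count curves, and the control 95th-percentile failure-count
boundary.

### Calibration expectations at n = 96

An empirical 5th-percentile cutoff from ~48 controls per sex stratum has
sampling SE ≈ √(pq/48)/φ(z₉₅) ≈ 0.31 SD, so held-out flag rates of
2–12% per parameter are compatible with a perfectly calibrated model;
the mean across parameters concentrates near 5–7% (percentile
interpolation at these n is slightly center-biased, and the age
regression adds a small overfit term). The calibration tests therefore
hold the across-parameter mean to the binomial 95% CI of 5% at the
held-out sample size and each single parameter to a 3-SD band whose
variance includes the cutoff-estimation term.

## Reliability statistics

ICC(2,1) — two-way random effects, single measure, absolute agreement —
is computed from the ANOVA mean squares (Shrout–Fleiss); the test suite
cross-checks it against pingouin's implementation and against the
variance-component oracle σ²s/(σ²s+σ²e) on simulated panels. Spearman
correlations are tie-corrected (Pearson on average ranks); p-values use
exact permutation enumeration for n ≤ 10 and the t-approximation above.
The Bonferroni family size is an explicit argument (the original family
of 12 tests gives the corrected level 0.05/12 ≈ 0.004); which 12 tests
composed that family is not fully enumerable from the source, hence the
argument.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` fit the normative model on 96
simulated controls at the 600 ms condition and classify 300–500 held-out
healthy subjects plus 30–40 severe subjects; catch recovery runs a
5-point onset grid in both directions at the severe gain; statistical
oracles use n = 96–200 samples. These sizes mirror the study's control
cohort where one is stated and otherwise were chosen as the smallest
sizes at which the binomial/Monte-Carlo bands above are meaningful.
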