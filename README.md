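# kaps — kinematic assessment of passive stretch

`kaps` quantifies post-stroke elbow spasticity from robot-driven passive
stretch trials. It is written for movement scientists and rehabilitation
researchers who want an objective alternative to ordinal bedside scales
(Modified Ashworth, Modified Tardieu): instead of a clinician's felt
resistance, the elbow is moved passively by an exoskeleton through an 80°
range (internal elbow angle 65–145°) at five commanded durations
(1500–600 ms) while joint angle and angular velocity are sampled at
1 kHz, and impairment is read off seven kinematic parameters against a
normative model of healthy-control performance.

Since robot hardware and patient data are rarely at hand, the package
includes a physics-based simulator of the whole protocol — a second-order
limb driven by the robot's PD position controller (proportional gain
30 Nm/rad, derivative 2.5 Nm/(rad/s), torque saturated at 13.2 Nm),
with configurable spastic reflex gain, contracture, creep, measurement
noise, and cohort-level age/sex structure — so every stage of the
pipeline can be exercised and validated end to end.

## The seven parameters

Each parameter is computed per movement direction (flexion / extension)
from 10 Hz zero-phase-Butterworth-filtered trials, three trials per
condition:

| # | Parameter | Definition |
|---|-----------|------------|
| 1 | Peak velocity | max \|θ̇\| during the movement |
| 2 | Final angle | mean angle over the last 50 ms before the next movement |
| 3 | Creep | signed continued travel after the stretch: extension `final − θ(1000 ms post-stretch)`, flexion the reverse; positive = further travel toward the target |
| 4 | Between-arm peak velocity difference | \|PV_affected − PV_reference\| |
| 5 | Between-arm final angle difference | affected − reference, signed |
| 6 | Between-arm creep difference | affected − reference, signed |
| 7 | Between-arm catch angle | excursion at which \|θ̇_affected − θ̇_nominal\| first exceeds the velocity-difference threshold (99th percentile of control performance; published value 50.1 °/s); positive for extension, negative for flexion |

The normative model (`kaps.NormativeModel`, a scikit-learn style
estimator) fits the control cohort per parameter: age regression (OLS),
Box-Cox normalization gated by Shapiro–Wilk, global robust-z outlier
removal, sex/handedness effect tests with sex-stratified cutoffs where
warranted, and one-tailed 5th/95th empirical percentile cutoffs. Subjects
are flagged per parameter (strictly beyond the cutoff), z-scored in
transformed space where defined, and summarised as failure counts over
the 14 parameter × direction slots. `kaps.reliability` adds ICC(2,1)
absolute-agreement inter-rater reliability and tie-corrected Spearman
correlations with Bonferroni control (0.05/12 → 0.004).

## Worked example

```python
from kaps import (CohortConfig, NormativeModel, ProtocolConfig,
                  assess_cohort, extract_cohort, simulate_cohort)

protocol = ProtocolConfig(durations=(600,))   # fastest stretch only

# 96 healthy controls -> normative model
meta, trials, _ = simulate_cohort(CohortConfig(n=96), seed=11, protocol=protocol)
model = NormativeModel().fit(extract_cohort(trials, meta))
print(model.n_controls_used_, model.velocity_threshold_)

# one simulated severe bilateral-spastic patient
meta_p, trials_p, _ = simulate_cohort(
    CohortConfig(n=2, impaired_fraction=1.0, severity="severe"),
    seed=99, protocol=protocol)
patient = extract_cohort(trials_p, meta_p)
report = assess_cohort(patient, model)[0]
print(report.failure_count, report.n_slots)
print(report.catch_angles["extension_catch_angle"])
print(report.z_scores["extension_peak_velocity"])
```

prints

```
controls used: 96 (outliers removed: 0)
velocity-difference threshold: 2.3 deg/s [fitted]
patient failure count: 12 of 14
extension catch angle: 28.6 deg after onset
extension peak-velocity z: 12.2
```

The patient fails 12 of the 14 slots — far beyond the control
95th-percentile failure-count boundary (2–3) — with a catch detected
28.6° after movement onset (the generating reflex engaged at 30°) and a
peak-velocity z-score of 12, i.e. the stretched arm moved far slower than
any healthy control of that age and sex. Note the fitted
velocity-difference threshold (2.3 °/s) is much lower than the published
50.1 °/s because simulated healthy arms are more symmetric than real
ones; see `docs/methods.md`.

A `kaps` command-line tool wraps the same pipeline
(`kaps simulate / validate / extract / build-norms / classify /
reliability / correlate`); trial files are plain CSV with a JSON metadata
sidecar.

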