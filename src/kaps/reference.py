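"""Published reference values from the original control study.

These are the printed normative cutoffs and threshold from the 96-control
cohort of the source study, provided as documented reference constants for
use when no control cohort is available. They are not recomputable from
data shipped with this package and are never used as test expectations for
simulated cohorts.

Conventions: the values are stored in this package's conventions — peak
velocity as magnitude (deg/s), internal elbow angle (deg, extension
increases the angle), creep positive toward the target, differences as
test arm minus reference arm (d_peak_velocity as an absolute value). Where
the study stratified by sex, cutoffs are given per sex ('M'/'F'); otherwise
under 'all'.
"""

from __future__ import annotations

#: Control-derived between-arm velocity difference threshold, deg/s
#: (99th percentile of control between-arm peak velocity differences).
REFERENCE_VELOCITY_THRESHOLD = 50.1

#: Published one-tailed cutoff values per parameter (see PARAMETER_TAILS in
#: :mod:`kaps.norms` for the impaired tail of each).
REFERENCE_CUTOFFS: dict[str, dict[str, float]] = {
    "extension_peak_velocity": {"all": 286.0},
    "extension_final_angle": {"M": 140.0, "F": 141.0},
    "extension_creep": {"all": 0.16},
    "extension_d_peak_velocity": {"M": 33.5, "F": 27.5},
    "extension_d_final_angle": {"all": -1.9},
    "extension_d_creep": {"M": 0.26, "F": 0.37},
    "flexion_peak_velocity": {"M": 240.0, "F": 255.0},
    "flexion_final_angle": {"M": 69.0, "F": 70.0},
    "flexion_creep": {"all": 0.28},
    "flexion_d_peak_velocity": {"M": 33.7, "F": 30.7},
    "flexion_d_final_angle": {"all": 2.06},
    "flexion_d_creep": {"all": 0.41},
}

#: Published control means per parameter (pooled or per sex), for context.
REFERENCE_CONTROL_MEANS: dict[str, dict[str, float]] = {
    "extension_peak_velocity": {"all": 306.0},
    "extension_final_angle": {"M": 143.0, "F": 144.0},
    "extension_creep": {"all": -0.05},
    "flexion_peak_velocity": {"M": 269.0, "F": 280.0},
    "flexion_final_angle": {"M": 68.0, "F": 67.0},
    "flexion_creep": {"all": -0.04},
}

#: Published inter-rater ICC(2,1) per parameter, for context.
REFERENCE_ICC: dict[str, float] = {
    "extension_peak_velocity": 0.90,
    "extension_final_angle": 0.86,
    "extension_creep": 0.66,
    "extension_d_peak_velocity": 0.95,
    "extension_d_final_angle": 0.91,
    "extension_d_creep": 0.74,
    "flexion_peak_velocity": 0.87,
    "flexion_final_angle": 0.84,
    "flexion_creep": 0.86,
    "flexion_d_peak_velocity": 0.88,
    "flexion_d_final_angle": 0.88,
    "flexion_d_creep": 0.79,
}
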