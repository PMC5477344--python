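"""Configuration objects for the passive-stretch simulator.

Angle convention: internal elbow angle in degrees, full extension toward
145 deg, full flexion toward 65 deg (extension increases the angle).
Movements are in the horizontal plane with full arm support, so no gravity
term appears anywhere in the dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

from .errors import ProtocolError

#: Internal elbow angles spanned by the protocol, degrees.
ANGLE_MIN = 65.0
ANGLE_MAX = 145.0

DEG2RAD = math.pi / 180.0
RAD2DEG = 180.0 / math.pi


@dataclass(frozen=True)
class RobotConfig:
    """Exoskeleton position-controller settings.

    The robot drives the elbow along a commanded trajectory with a PD loop
    plus an inertial feedforward term, saturated at a safety torque limit.
    After the nominal movement ends it keeps pulling toward the target with
    a soft proportional gain for up to ``timeout_ms`` after movement onset.

    Parameters
    ----------
    kp : float
        Proportional gain during the movement, Nm/rad.
    kd : float
        Derivative gain, Nm/(rad/s). Also retained during the hold phase to
        keep the hold dynamics well damped.
    hold_gain : float
        Post-stretch proportional pull toward the target angle, Nm/deg.
    torque_limit : float
        Saturation of the commanded motor torque, Nm.
    timeout_ms : float
        How long after movement onset the controller keeps producing torque
        when the target has not been reached, ms.
    inertia_estimate : float
        Inertia (kg m^2) used by the feedforward term; a single fixed
        estimate, not personalised.
    reach_tolerance_deg : float
        |angle - target| at or below which the target counts as reached.
    """

    kp: float = 30.0
    kd: float = 2.5
    hold_gain: float = 0.26
    torque_limit: float = 13.2
    timeout_ms: float = 7000.0
    inertia_estimate: float = 0.12
    reach_tolerance_deg: float = 1.0

    def __post_init__(self) -> None:
        if self.kp <= 0:
            raise ProtocolError("kp must be positive")
        if self.kd < 0:
            raise ProtocolError("kd must be non-negative")
        if self.torque_limit <= 0:
            raise ProtocolError("torque_limit must be positive")
        if self.hold_gain < 0:
            raise ProtocolError("hold_gain must be non-negative")
        if self.timeout_ms <= 0:
            raise ProtocolError("timeout_ms must be positive")
        if self.inertia_estimate <= 0:
            raise ProtocolError("inertia_estimate must be positive")


@dataclass(frozen=True)
class LimbConfig:
    """Mechanical model of one arm as seen at the elbow.

    A second-order limb: inertia plus passive viscous damping, optionally
    augmented with a stretch-reflex element (a velocity-proportional
    resistance that latches on after ``catch_onset_excursion`` degrees of
    travel and decays with ``release_time_constant`` once motion stalls)
    and a one-sided contracture spring engaging beyond
    ``contracture_limit`` degrees of extension.

    ``spastic_gain == 0`` with contracture disabled defines a healthy limb.
    """

    inertia: float = 0.12                 # kg m^2 about the elbow
    passive_damping: float = 0.25         # Nm/(rad/s)
    spastic_gain: float = 0.0             # Nm/(rad/s)
    catch_onset_excursion: float = 30.0   # deg of travel before the reflex engages
    release_time_constant: float = 1.5    # s, decay of the reflex once stalled
    contracture_limit: float | None = None  # deg, extension beyond this loads the spring
    contracture_stiffness: float = 0.0      # Nm/deg
    noise_sd: float = 0.1                 # deg, additive measurement noise on angle

    def __post_init__(self) -> None:
        if self.inertia <= 0:
            raise ProtocolError("inertia must be positive")
        for name in ("passive_damping", "spastic_gain", "contracture_stiffness"):
            if getattr(self, name) < 0:
                raise ProtocolError(f"{name} must be non-negative")
        if self.release_time_constant <= 0:
            raise ProtocolError("release_time_constant must be positive")
        if self.noise_sd < 0:
            raise ProtocolError("noise_sd must be non-negative")
        if self.contracture_limit is not None and not (
            ANGLE_MIN <= self.contracture_limit <= ANGLE_MAX
        ):
            raise ProtocolError(
                f"contracture_limit must lie in [{ANGLE_MIN}, {ANGLE_MAX}] deg"
            )

    @property
    def healthy(self) -> bool:
        return self.spastic_gain == 0 and self.contracture_limit is None


@dataclass(frozen=True)
class ProtocolConfig:
    """Trial structure of the passive-stretch assessment.

    One trial is a flexion movement from ``start_angle`` to ``end_angle``,
    an ``intra_trial_wait`` hold, an extension movement back, and an
    ``inter_trial_wait`` hold. Three trials are run at each nominal
    duration, slowest block first.
    """

    start_angle: float = 145.0
    end_angle: float = 65.0
    durations: tuple[int, ...] = (1500, 1200, 1000, 800, 600)
    trials_per_duration: int = 3
    intra_trial_wait: float = 1500.0
    inter_trial_wait: float = 3000.0
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("start_angle", "end_angle"):
            a = getattr(self, name)
            if not (ANGLE_MIN <= a <= ANGLE_MAX):
                raise ProtocolError(f"{name} must lie in [{ANGLE_MIN}, {ANGLE_MAX}] deg")
        if any(d <= 0 for d in self.durations):
            raise ProtocolError("durations must be positive")
        if self.trials_per_duration < 1:
            raise ProtocolError("trials_per_duration must be >= 1")
        if self.intra_trial_wait < 0 or self.inter_trial_wait < 0:
            raise ProtocolError("waits must be non-negative")
        if self.sample_rate < 100:
            raise ProtocolError("sample_rate must allow low-pass filtering (>= 100 Hz)")

    def to_dict(self) -> dict:
        return asdict(self)


#: Affected-arm presets used by the cohort generator. Severity scales the
#: reflex gain, pulls the catch earlier, and (for severe) adds contracture.
SEVERITY_PRESETS: dict[str, dict] = {
    "mild": dict(spastic_gain=3.0, catch_onset_excursion=50.0,
                 release_time_constant=1.0, passive_damping_extra=0.1),
    "moderate": dict(spastic_gain=7.0, catch_onset_excursion=40.0,
                     release_time_constant=1.2, passive_damping_extra=0.3),
    "severe": dict(spastic_gain=15.0, catch_onset_excursion=30.0,
                   release_time_constant=1.5, passive_damping_extra=0.5,
                   contracture_limit=120.0, contracture_stiffness=2.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Population structure for simulated cohorts.

    Between-subject variation is carried by passive damping and limb
    inertia; between-arm variation by damping alone (inter-arm inertia
    asymmetry is physiologically negligible). Sex enters through inertia
    (forearm-plus-hand moment about the elbow), age optionally through a
    linear slope on damping.
    """

    n: int = 96
    age_range: tuple[float, float] = (20.0, 80.0)
    female_fraction: float = 0.5
    right_handed_fraction: float = 0.9
    inertia_male_mean: float = 0.14
    inertia_female_mean: float = 0.105
    inertia_sd: float = 0.015
    damping_mean: float = 0.25
    damping_sd: float = 0.06
    damping_arm_sd: float = 0.02
    damping_age_slope: float = 0.0      # Nm/(rad/s) per year, about the cohort mid-age
    damping_sex_offset: float = 0.0     # male minus female additive offset
    noise_sd: float = 0.1
    impaired_fraction: float = 0.0
    severity: str = "severe"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ProtocolError("cohort size must be >= 2")
        for name in ("female_fraction", "right_handed_fraction", "impaired_fraction"):
            f = getattr(self, name)
            if not (0.0 <= f <= 1.0):
                raise ProtocolError(f"{name} must lie in [0, 1]")
        if self.age_range[1] < self.age_range[0]:
            raise ProtocolError("age_range must be (low, high)")
        if self.severity not in SEVERITY_PRESETS:
            raise ProtocolError(
                f"severity must be one of {sorted(SEVERITY_PRESETS)}"
            )

    @property
    def mid_age(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])
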