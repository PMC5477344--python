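"""Physics-based generator of passive-stretch trials and cohorts.

The robot drives a second-order limb through an 80-degree elbow stretch
along a half-cosine commanded trajectory (the simplest sine-based profile
with zero endpoint velocities). During the movement the controller is a PD
loop with inertial feedforward, saturated at the safety torque limit; after
the nominal movement end it switches to a soft proportional pull toward the
target (0.26 Nm/deg) with the derivative term retained for damping. If the
target is not reached by the scheduled hold end, the controller persists —
and the recording continues — until the target is reached or 7000 ms after
movement onset, and the angle reached then becomes the next movement's
start angle.

Spasticity is modelled as a gated velocity-proportional reflex torque: it
latches on after a configurable excursion (producing the catch — an abrupt
velocity drop at a reproducible angle), resists the remainder of the
stretch (reduced peak velocity), opposes the hold-phase pull (slow creep
toward the target), and decays exponentially once motion stalls (release).
Contracture is a one-sided spring engaging beyond an extension limit.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from numba import njit

from .config import (
    ANGLE_MAX,
    ANGLE_MIN,
    DEG2RAD,
    RAD2DEG,
    SEVERITY_PRESETS,
    CohortConfig,
    LimbConfig,
    ProtocolConfig,
    RobotConfig,
)
from .errors import ProtocolError, SimulationInstabilityError
from .store import TrialRecording

__all__ = [
    "commanded_profile",
    "simulate_trial",
    "simulate_subject",
    "simulate_cohort",
    "limb_from_severity",
]

#: |angular velocity| (rad/s) beyond which the integration is declared divergent.
_OMEGA_SANITY = 100.0
#: |angular velocity| (deg/s) below which the latched reflex is "stalled" and decays.
_STALL_DEG_S = 10.0


def commanded_profile(t_rel, duration: float, start_angle: float, end_angle: float):
    """Commanded angle and velocity of the half-cosine stretch profile.

    theta(t) = theta_s + (theta_e - theta_s) * (1 - cos(pi t / T)) / 2 for
    t <= T, clamped at theta_e afterwards; the velocity is the analytic
    derivative (a single sine lobe, zero at both endpoints).

    Parameters
    ----------
    t_rel : float or array
        Time since movement onset, ms.
    duration : float
        Nominal movement duration T, ms.
    start_angle, end_angle : float
        Commanded endpoints, deg.

    Returns
    -------
    (angle_deg, velocity_deg_s) matching the shape of ``t_rel``.
    """
    if duration <= 0:
        raise ProtocolError("duration must be positive")
    t = np.asarray(t_rel, dtype=float)
    if np.any(t < 0):
        raise ProtocolError("t_rel must be non-negative")
    T = duration / 1000.0
    ts = t / 1000.0
    span = end_angle - start_angle
    phase = np.pi * np.minimum(ts, T) / T
    angle = start_angle + span * (1.0 - np.cos(phase)) / 2.0
    velocity = span * np.pi / (2.0 * T) * np.sin(phase)
    velocity = np.where(ts >= T, 0.0, velocity)
    if np.isscalar(t_rel):
        return float(angle), float(velocity)
    return angle, velocity


@njit(cache=True)
def _integrate(dt, n_sched, n_max, T, th_s, th_e,
               kp, kd, khold, tau_lim, i_est,
               inertia, b, g0, catch_exc, tau_rel, con_lim, k_con, con_on,
               reach_tol, stall):
    """Fixed-step RK4 integration of one movement plus hold (all radians/SI).

    Returns (n_used, status, theta, omega, tau_robot); status 1 flags a
    numerical blow-up.
    """
    theta = np.empty(n_max)
    omega = np.empty(n_max)
    tau_r = np.empty(n_max)
    th = th_s
    om = 0.0
    g = 0.0
    latched = False
    decay = math.exp(-dt / tau_rel)
    span = th_e - th_s
    n_used = n_max
    status = 0

    for i in range(n_max):
        t = i * dt
        # record the sample, with the robot torque at the recorded state
        if t <= T:
            phase = math.pi * t / T
            thc = th_s + span * (1.0 - math.cos(phase)) / 2.0
            dthc = span * math.pi / (2.0 * T) * math.sin(phase)
            ddthc = span * math.pi * math.pi / (2.0 * T * T) * math.cos(phase)
            tr = kp * (thc - th) + kd * (dthc - om) + i_est * ddthc
        else:
            tr = khold * (th_e - th) + kd * (0.0 - om)
        if tr > tau_lim:
            tr = tau_lim
        elif tr < -tau_lim:
            tr = -tau_lim
        theta[i] = th
        omega[i] = om
        tau_r[i] = tr

        # stopping rule: run the scheduled window, then persist until the
        # target is reached or the controller timeout elapses
        if i >= n_sched - 1:
            if abs(th - th_e) <= reach_tol or i == n_max - 1:
                n_used = i + 1
                break

        # one RK4 step with the reflex gain frozen within the step
        th_k = th
        om_k = om
        k1t = om_k
        k1o = _accel(t, th_k, om_k, T, th_s, th_e, span, kp, kd, khold,
                     tau_lim, i_est, inertia, b, g, con_lim, k_con, con_on)
        k2t = om_k + 0.5 * dt * k1o
        k2o = _accel(t + 0.5 * dt, th_k + 0.5 * dt * k1t, om_k + 0.5 * dt * k1o,
                     T, th_s, th_e, span, kp, kd, khold, tau_lim, i_est,
                     inertia, b, g, con_lim, k_con, con_on)
        k3t = om_k + 0.5 * dt * k2o
        k3o = _accel(t + 0.5 * dt, th_k + 0.5 * dt * k2t, om_k + 0.5 * dt * k2o,
                     T, th_s, th_e, span, kp, kd, khold, tau_lim, i_est,
                     inertia, b, g, con_lim, k_con, con_on)
        k4t = om_k + dt * k3o
        k4o = _accel(t + dt, th_k + dt * k3t, om_k + dt * k3o,
                     T, th_s, th_e, span, kp, kd, khold, tau_lim, i_est,
                     inertia, b, g, con_lim, k_con, con_on)
        th = th + dt / 6.0 * (k1t + 2.0 * k2t + 2.0 * k3t + k4t)
        om = om + dt / 6.0 * (k1o + 2.0 * k2o + 2.0 * k3o + k4o)

        if abs(om) > _OMEGA_SANITY:
            n_used = i + 1
            status = 1
            break

        # reflex latch and release
        if g0 > 0.0 and not latched and abs(th - th_s) >= catch_exc:
            latched = True
            g = g0
        if latched and abs(om) < stall:
            g *= decay

    return n_used, status, theta[:n_used], omega[:n_used], tau_r[:n_used]


@njit(cache=True, inline="always")
def _accel(t, th, om, T, th_s, th_e, span, kp, kd, khold, tau_lim, i_est,
           inertia, b, g, con_lim, k_con, con_on):
    if t <= T:
        phase = math.pi * t / T
        thc = th_s + span * (1.0 - math.cos(phase)) / 2.0
        dthc = span * math.pi / (2.0 * T) * math.sin(phase)
        ddthc = span * math.pi * math.pi / (2.0 * T * T) * math.cos(phase)
        tr = kp * (thc - th) + kd * (dthc - om) + i_est * ddthc
    else:
        tr = khold * (th_e - th) + kd * (0.0 - om)
    if tr > tau_lim:
        tr = tau_lim
    elif tr < -tau_lim:
        tr = -tau_lim
    tau = tr - b * om - g * om
    if con_on and th > con_lim:
        tau -= k_con * (th - con_lim)
    return tau / inertia


def simulate_trial(limb: LimbConfig, robot: RobotConfig, protocol: ProtocolConfig,
                   direction: str, duration_ms: float, start_angle: float,
                   rng: np.random.Generator | int, *,
                   subject_id: str = "sim", arm: str = "affected",
                   trial_index: int = 1) -> TrialRecording:
    """Simulate one movement plus hold and return the recording.

    ``rng`` may be a seed or a Generator (noise is the only stochastic
    element; the dynamics are deterministic). The achieved angle at the end
    of the recording is the next movement's start angle (exposed as the
    last recorded angle / ``target_angle_deg`` per the timeout rule).
    """
    if direction not in ("flexion", "extension"):
        raise ProtocolError(f"unknown direction {direction!r}")
    if not (ANGLE_MIN - 5.0 <= start_angle <= ANGLE_MAX + 5.0):
        raise ProtocolError(f"start_angle {start_angle} outside physical range")
    if duration_ms <= 0:
        raise ProtocolError("duration must be positive")
    if robot.timeout_ms < duration_ms:
        raise ProtocolError("timeout_ms must cover the nominal duration")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    target = protocol.end_angle if direction == "flexion" else protocol.start_angle
    wait = (protocol.intra_trial_wait if direction == "flexion"
            else protocol.inter_trial_wait)
    dt = 1.0 / protocol.sample_rate
    n_sched = int(round((duration_ms + wait) / 1000.0 / dt))
    n_max = int(round(robot.timeout_ms / 1000.0 / dt))

    con_on = limb.contracture_limit is not None and limb.contracture_stiffness > 0
    n_used, status, th, om, tau = _integrate(
        dt, n_sched, n_max, duration_ms / 1000.0,
        start_angle * DEG2RAD, target * DEG2RAD,
        robot.kp, robot.kd, robot.hold_gain * RAD2DEG, robot.torque_limit,
        robot.inertia_estimate,
        limb.inertia, limb.passive_damping, limb.spastic_gain,
        limb.catch_onset_excursion * DEG2RAD, limb.release_time_constant,
        (limb.contracture_limit or 0.0) * DEG2RAD,
        limb.contracture_stiffness * RAD2DEG, con_on,
        robot.reach_tolerance_deg * DEG2RAD, _STALL_DEG_S * DEG2RAD,
    )
    if status != 0:
        raise SimulationInstabilityError(
            f"angular velocity exceeded {_OMEGA_SANITY} rad/s "
            f"(inertia={limb.inertia}, damping={limb.passive_damping}, "
            f"spastic_gain={limb.spastic_gain}, "
            f"contracture_stiffness={limb.contracture_stiffness})"
        )
    angle = th * RAD2DEG
    if limb.noise_sd > 0:
        angle = angle + rng.normal(0.0, limb.noise_sd, size=n_used)
    trial = TrialRecording(
        subject_id=subject_id, arm=arm, direction=direction,
        nominal_duration_ms=int(duration_ms), trial_index=trial_index,
        time_ms=np.arange(n_used, dtype=float),
        angle_deg=angle, velocity_deg_s=om * RAD2DEG,
        onset_ms=0.0, start_angle_deg=start_angle, target_angle_deg=target,
        next_onset_ms=float(n_used),
    )
    trial._achieved_end_angle = float(th[-1] * RAD2DEG)  # ground truth for chaining
    trial._robot_torque_nm = tau
    trial._true_angle_deg = th * RAD2DEG
    return trial


def simulate_subject(test_limb: LimbConfig, reference_limb: LimbConfig,
                     robot: RobotConfig | None = None,
                     protocol: ProtocolConfig | None = None,
                     seed: int | np.random.Generator = 0, *,
                     subject_id: str = "sim",
                     arm_labels: tuple[str, str] = ("affected", "less_affected"),
                     ) -> list[TrialRecording]:
    """Run the full protocol on both arms (test arm first).

    Per arm: three trials at each nominal duration, slowest block first;
    each trial is a flexion then an extension movement, chaining the
    achieved end angle into the next movement's start angle. Deterministic
    given the seed.
    """
    robot = robot or RobotConfig()
    protocol = protocol or ProtocolConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out: list[TrialRecording] = []
    for limb, arm in ((test_limb, arm_labels[0]), (reference_limb, arm_labels[1])):
        start = protocol.start_angle
        for duration in protocol.durations:
            for k in range(1, protocol.trials_per_duration + 1):
                for direction in ("flexion", "extension"):
                    tr = simulate_trial(
                        limb, robot, protocol, direction, duration, start, rng,
                        subject_id=subject_id, arm=arm, trial_index=k,
                    )
                    start = tr._achieved_end_angle
                    out.append(tr)
    return out


def limb_from_severity(severity: str, base: LimbConfig) -> LimbConfig:
    """Apply an impairment preset to a baseline (healthy) limb."""
    preset = dict(SEVERITY_PRESETS[severity])
    extra = preset.pop("passive_damping_extra", 0.0)
    return LimbConfig(
        inertia=base.inertia,
        passive_damping=base.passive_damping + extra,
        noise_sd=base.noise_sd,
        **preset,
    )


def simulate_cohort(config: CohortConfig, seed: int = 0, *,
                    robot: RobotConfig | None = None,
                    protocol: ProtocolConfig | None = None):
    """Simulate a cohort of subjects; returns (metadata, trials, ground_truth).

    ``metadata`` is a tidy table (subject_id, age, sex, handedness, group);
    ``trials`` maps subject_id to that subject's recordings; ``ground_truth``
    maps subject_id to the generating limb configurations (a test oracle).

    Impaired subjects receive the configured severity preset on the test
    arm (labelled affected/less_affected); controls use dominant /
    non-dominant labels with independently jittered healthy arms.
    """
    import warnings as _warnings

    robot = robot or RobotConfig()
    protocol = protocol or ProtocolConfig()
    if (config.age_range[1] == config.age_range[0]
            and config.damping_age_slope != 0.0):
        _warnings.warn("zero age range with a nonzero age slope: "
                       "the slope is unidentifiable", stacklevel=2)
    rng = np.random.default_rng(seed)
    n_impaired = int(round(config.impaired_fraction * config.n))
    rows, trials, truth = [], {}, {}
    for i in range(config.n):
        sid = f"S{i:03d}"
        age = rng.uniform(*config.age_range)
        sex = "F" if rng.random() < config.female_fraction else "M"
        hand = "R" if rng.random() < config.right_handed_fraction else "L"
        inertia_mean = (config.inertia_female_mean if sex == "F"
                        else config.inertia_male_mean)
        inertia = max(rng.normal(inertia_mean, config.inertia_sd), 0.04)
        damp_mid = (config.damping_mean
                    + config.damping_age_slope * (age - config.mid_age)
                    + (config.damping_sex_offset if sex == "M" else 0.0)
                    + rng.normal(0.0, config.damping_sd))
        arms = []
        for _ in range(2):
            d = max(damp_mid + rng.normal(0.0, config.damping_arm_sd), 0.01)
            arms.append(LimbConfig(inertia=inertia, passive_damping=d,
                                   noise_sd=config.noise_sd))
        impaired = i < n_impaired
        if impaired:
            test, ref = limb_from_severity(config.severity, arms[0]), arms[1]
            labels = ("affected", "less_affected")
        else:
            test, ref = arms[0], arms[1]
            labels = ("non_dominant", "dominant")
        sub_seed = int(rng.integers(0, 2**31 - 1))
        trials[sid] = simulate_subject(
            test, ref, robot, protocol, sub_seed,
            subject_id=sid, arm_labels=labels,
        )
        rows.append({"subject_id": sid, "age": age, "sex": sex,
                     "handedness": hand,
                     "group": "stroke" if impaired else "control"})
        truth[sid] = {"test_limb": _limb_dict(test),
                      "reference_limb": _limb_dict(ref),
                      "impaired": impaired, "seed": sub_seed}
    metadata = pd.DataFrame(rows)
    return metadata, trials, truth


def _limb_dict(limb: LimbConfig) -> dict:
    from dataclasses import asdict
    return asdict(limb)
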