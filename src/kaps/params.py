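"""The seven passive-stretch kinematic parameters.

Per movement direction (flexion / extension): three single-arm measures —
peak velocity, final angle, creep — computed on the test arm, three signed
or absolute between-arm differences, and the between-arm catch angle
detected from the velocity difference against the reference arm.

All computations expect low-pass-filtered trials (see
:func:`kaps.store.filter_trial`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .store import (
    REFERENCE_ARMS,
    TEST_ARMS,
    MovementWindows,
    TrialRecording,
    filter_trial,
    segment,
)

#: Fallback velocity-difference threshold, deg/s, when no fitted control
#: threshold is supplied (the published control-derived value).
DEFAULT_VELOCITY_THRESHOLD = 50.1

SINGLE_ARM_PARAMS = ("peak_velocity", "final_angle", "creep")
DIFFERENCE_PARAMS = ("d_peak_velocity", "d_final_angle", "d_creep")


@dataclass
class ParameterSet:
    """Single-arm parameters for one direction at one nominal duration."""

    direction: str
    duration_ms: int
    peak_velocity: float        # deg/s, magnitude
    final_angle: float          # deg
    creep: float                # deg, positive = continued travel toward the target
    per_trial: dict[str, list[float]] = field(default_factory=dict)


@dataclass
class BilateralParameters:
    """Between-arm parameters for one direction (test arm minus reference)."""

    direction: str
    duration_ms: int
    d_peak_velocity: float      # deg/s, absolute
    d_final_angle: float        # deg, signed
    d_creep: float              # deg, signed
    catch_angle: float | None   # deg of excursion; None when no crossing


def peak_velocity(trial: TrialRecording, windows: MovementWindows,
                  timeout_ms: float = 7000.0) -> float:
    """Maximum |angular velocity| over the movement.

    The search window runs from onset through the hold (capped at the
    controller timeout) so that movements the controller completes after
    the nominal duration are still captured; hold-phase velocities are
    orders of magnitude below the stretch peak and never dominate.
    """
    lo, hi = windows.movement[0], min(windows.hold_end,
                                      windows.movement[0] + int(timeout_ms))
    if hi <= lo:
        raise ParameterError("empty movement window")
    v = np.asarray(trial.velocity_deg_s)[lo:hi + 1]
    return float(np.max(np.abs(v)))


def final_angle(trial: TrialRecording, windows: MovementWindows,
                terminal_ms: int = 50) -> float:
    """Mean filtered angle over the last ``terminal_ms`` before the next onset."""
    hi = windows.hold_end
    lo = hi - terminal_ms + 1
    if lo < windows.movement[1]:
        warnings.warn("hold shorter than the terminal averaging window; "
                      "falling back to the last sample", stacklevel=2)
        lo = hi
    return float(np.mean(np.asarray(trial.angle_deg)[lo:hi + 1]))


def creep(trial: TrialRecording, windows: MovementWindows,
          direction: str | None = None) -> float:
    """Direction-signed creep.

    Flexion: (angle at 1000 ms post-stretch) - final angle.
    Extension: final angle - (angle at 1000 ms post-stretch).
    Positive creep always means continued travel toward the target in the
    imposed direction.
    """
    direction = direction or trial.direction
    if direction not in ("flexion", "extension"):
        raise ParameterError(f"unknown direction {direction!r}")
    post = float(np.asarray(trial.angle_deg)[windows.post_stretch_sample])
    fin = final_angle(trial, windows)
    if windows.post_stretch_clipped:
        warnings.warn("post-stretch sample was clipped to hold end; "
                      "creep computed on the clipped sample", stacklevel=2)
    if direction == "flexion":
        return post - fin
    return fin - post


def aggregate_trials(values, method: str = "mean") -> float:
    """Collapse per-trial values to one number (default: mean of the 3 trials)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ParameterError("no trial values to aggregate")
    if method == "mean":
        return float(np.mean(values))
    if method == "median":
        return float(np.median(values))
    raise ParameterError(f"unknown aggregation method {method!r}")


def single_arm_parameters(trials: list[TrialRecording], *,
                          aggregate: str = "mean",
                          prefiltered: bool = True) -> ParameterSet:
    """Compute the three single-arm measures across same-condition trials."""
    if not trials:
        raise ParameterError("no trials given")
    direction = trials[0].direction
    duration = trials[0].nominal_duration_ms
    if any(t.direction != direction or t.nominal_duration_ms != duration
           for t in trials):
        raise ParameterError("trials mix directions or durations")
    per = {"peak_velocity": [], "final_angle": [], "creep": []}
    for tr in trials:
        tf = tr if prefiltered else filter_trial(tr)
        w = segment(tf)
        per["peak_velocity"].append(peak_velocity(tf, w))
        per["final_angle"].append(final_angle(tf, w))
        per["creep"].append(creep(tf, w))
    return ParameterSet(
        direction=direction, duration_ms=duration,
        peak_velocity=aggregate_trials(per["peak_velocity"], aggregate),
        final_angle=aggregate_trials(per["final_angle"], aggregate),
        creep=aggregate_trials(per["creep"], aggregate),
        per_trial=per,
    )


def between_arm_differences(test: ParameterSet, reference: ParameterSet
                            ) -> BilateralParameters:
    """Between-arm differences (test/affected minus reference); catch excluded."""
    if test.direction != reference.direction:
        raise ParameterError("direction mismatch between arms")
    if test.duration_ms != reference.duration_ms:
        raise ParameterError("duration mismatch between arms")
    return BilateralParameters(
        direction=test.direction, duration_ms=test.duration_ms,
        d_peak_velocity=abs(test.peak_velocity - reference.peak_velocity),
        d_final_angle=test.final_angle - reference.final_angle,
        d_creep=test.creep - reference.creep,
        catch_angle=None,
    )


def catch_angle(test_trials: list[TrialRecording],
                reference_trials: list[TrialRecording],
                threshold: float = DEFAULT_VELOCITY_THRESHOLD, *,
                mode: str = "trial_to_mean") -> float | None:
    """Between-arm catch angle, or None when no trial crosses the threshold.

    The reference arm's nominal velocity profile is the time-aligned (at
    command onset) mean across its trials (``mode='trial_to_mean'``) or the
    index-matched single trial (``mode='trial_to_trial'``). For each test
    trial the first sample in the movement window where the absolute
    between-arm velocity difference exceeds ``threshold`` is converted to
    angular excursion from that trial's start angle; the median across
    crossing trials is reported. Sign: positive for extension, negative for
    flexion.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    if not test_trials or not reference_trials:
        raise ParameterError("both arms need at least one trial")
    direction = test_trials[0].direction
    duration = test_trials[0].nominal_duration_ms
    for tr in (*test_trials, *reference_trials):
        if tr.direction != direction or tr.nominal_duration_ms != duration:
            raise ParameterError("trials mix directions or durations")
    if mode not in ("trial_to_mean", "trial_to_trial"):
        raise ParameterError(f"unknown catch mode {mode!r}")

    def movement_velocity(tr: TrialRecording) -> np.ndarray:
        w = segment(tr)
        return np.asarray(tr.velocity_deg_s)[w.movement[0]:w.movement[1] + 1]

    ref_v = [movement_velocity(tr) for tr in reference_trials]
    n = min(len(v) for v in ref_v)
    nominal = np.mean([v[:n] for v in ref_v], axis=0)

    crossings: list[float] = []
    for i, tr in enumerate(test_trials):
        w = segment(tr)
        v = np.asarray(tr.velocity_deg_s)[w.movement[0]:w.movement[1] + 1]
        if mode == "trial_to_trial":
            ref = ref_v[i % len(ref_v)]
            m = min(len(v), len(ref))
            diff = np.abs(v[:m] - ref[:m])
        else:
            m = min(len(v), n)
            diff = np.abs(v[:m] - nominal[:m])
        idx = np.flatnonzero(diff > threshold)
        if idx.size == 0:
            continue
        k = w.movement[0] + int(idx[0])
        excursion = float(np.asarray(tr.angle_deg)[k] - tr.start_angle_deg)
        crossings.append(excursion)
    if not crossings:
        return None
    return float(np.median(crossings))


def velocity_difference_peak(test_trials: list[TrialRecording],
                             reference_trials: list[TrialRecording]) -> float:
    """Peak of the absolute between-arm velocity difference trace, deg/s.

    Uses the same onset-aligned nominal reference profile as
    :func:`catch_angle` (mean across reference trials) and reports the
    median across test trials of the movement-window maximum. This is the
    quantity whose control 99th percentile defines the catch-detection
    threshold; it differs from ``d_peak_velocity`` (the absolute
    difference of the two arms' peak velocities), which is always the
    smaller of the two.
    """
    if not test_trials or not reference_trials:
        raise ParameterError("both arms need at least one trial")

    def movement_velocity(tr: TrialRecording) -> np.ndarray:
        w = segment(tr)
        return np.asarray(tr.velocity_deg_s)[w.movement[0]:w.movement[1] + 1]

    ref_v = [movement_velocity(tr) for tr in reference_trials]
    n = min(len(v) for v in ref_v)
    nominal = np.mean([v[:n] for v in ref_v], axis=0)
    maxima = []
    for tr in test_trials:
        v = movement_velocity(tr)
        m = min(len(v), n)
        maxima.append(float(np.max(np.abs(v[:m] - nominal[:m]))))
    return float(np.median(maxima))


# ---------------------------------------------------------------------------
# subject / cohort extraction


def _group_trials(trials: list[TrialRecording], duration: int):
    """Split one subject's trials into {(role, direction): [trials]}."""
    groups: dict[tuple[str, str], list[TrialRecording]] = {}
    for tr in trials:
        if tr.nominal_duration_ms != duration:
            continue
        if tr.arm in TEST_ARMS:
            role = "test"
        elif tr.arm in REFERENCE_ARMS:
            role = "reference"
        else:  # pragma: no cover - guarded by schema validation
            raise ParameterError(f"unknown arm label {tr.arm!r}")
        groups.setdefault((role, tr.direction), []).append(tr)
    return groups


def extract_subject(trials: list[TrialRecording], *, duration: int = 600,
                    threshold: float = DEFAULT_VELOCITY_THRESHOLD,
                    cutoff_hz: float = 10.0, aggregate: str = "mean",
                    catch_mode: str = "trial_to_mean") -> dict[str, dict[str, float]]:
    """All seven parameters for one subject at one nominal duration.

    Returns ``{direction: {parameter: value}}``; ``catch_angle`` is NaN when
    no threshold crossing occurred.
    """
    filtered = [filter_trial(tr, cutoff_hz) for tr in trials
                if tr.nominal_duration_ms == duration]
    groups = _group_trials(filtered, duration)
    out: dict[str, dict[str, float]] = {}
    for direction in ("flexion", "extension"):
        test = groups.get(("test", direction))
        ref = groups.get(("reference", direction))
        if not test or not ref:
            raise ParameterError(
                f"subject is missing {direction} trials at {duration} ms "
                "for one of the arms"
            )
        ps_test = single_arm_parameters(test, aggregate=aggregate)
        ps_ref = single_arm_parameters(ref, aggregate=aggregate)
        bil = between_arm_differences(ps_test, ps_ref)
        catch = catch_angle(test, ref, threshold, mode=catch_mode)
        vdp = velocity_difference_peak(test, ref)
        out[direction] = {
            "peak_velocity": ps_test.peak_velocity,
            "final_angle": ps_test.final_angle,
            "creep": ps_test.creep,
            "d_peak_velocity": bil.d_peak_velocity,
            "d_final_angle": bil.d_final_angle,
            "d_creep": bil.d_creep,
            "catch_angle": np.nan if catch is None else catch,
            "velocity_difference_peak": vdp,
        }
        # per-trial single-arm values (test arm) for inspection / export
        for pname, values in ps_test.per_trial.items():
            for k, v in enumerate(values, start=1):
                out[direction][f"{pname}_trial{k}"] = v
    return out


def extract_cohort(trials_by_subject: dict[str, list[TrialRecording]],
                   metadata=None, *, duration: int = 600,
                   threshold: float = DEFAULT_VELOCITY_THRESHOLD,
                   cutoff_hz: float = 10.0, aggregate: str = "mean",
                   catch_mode: str = "trial_to_mean"):
    """Wide per-subject parameter table for a cohort.

    Columns are ``{direction}_{parameter}`` for the seven parameters in
    both directions; demographic columns are merged from ``metadata`` (a
    DataFrame with a ``subject_id`` column) when given.
    """
    import pandas as pd

    rows = []
    for sid, trials in trials_by_subject.items():
        per_dir = extract_subject(
            trials, duration=duration, threshold=threshold,
            cutoff_hz=cutoff_hz, aggregate=aggregate, catch_mode=catch_mode,
        )
        row: dict[str, float | str] = {"subject_id": sid}
        for direction, values in per_dir.items():
            for name, value in values.items():
                row[f"{direction}_{name}"] = value
        rows.append(row)
    table = pd.DataFrame(rows)
    if metadata is not None:
        table = table.merge(metadata, on="subject_id", how="left")
    return table
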