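"""Kinematic parameter computations: single-arm, between-arm, catch."""

import numpy as np
import pytest

from kaps.config import LimbConfig, ProtocolConfig, RobotConfig
from kaps.errors import ParameterError
from kaps.params import (
    DEFAULT_VELOCITY_THRESHOLD,
    ParameterSet,
    aggregate_trials,
    between_arm_differences,
    catch_angle,
    creep,
    extract_cohort,
    extract_subject,
    final_angle,
    peak_velocity,
    single_arm_parameters,
    velocity_difference_peak,
)
from kaps.simulate import simulate_cohort, simulate_trial
from kaps.store import filter_trial, segment

from conftest import make_synthetic_trial


class TestPeakVelocity:
    def test_magnitude_of_constant_velocity(self):
        tr = make_synthetic_trial(velocity=np.full(3600, -100.0),
                                  angle=np.full(3600, 100.0))
        assert peak_velocity(tr, segment(tr)) == 100.0

    def test_spike_outside_search_window_ignored(self):
        v = np.zeros(9000)
        v[200] = 50.0
        v[8500] = 500.0  # beyond the controller timeout
        tr = make_synthetic_trial(n=9000, velocity=v,
                                  angle=np.full(9000, 100.0))
        assert peak_velocity(tr, segment(tr)) == 50.0

    def test_healthy_trial_tracks_analytic_command_peak(self, healthy_extension):
        tr = filter_trial(healthy_extension)
        pv = peak_velocity(tr, segment(tr))
        assert pv == pytest.approx(np.pi * 80 / (2 * 0.6), rel=0.10)


class TestFinalAngle:
    def test_constant_hold(self):
        tr = make_synthetic_trial(angle=np.full(3600, 143.0))
        assert final_angle(tr, segment(tr)) == pytest.approx(143.0)

    def test_mean_of_linear_terminal_ramp(self):
        angle = np.full(3600, 140.0)
        # last 50 samples ramp linearly up to 145
        angle[-50:] = np.linspace(145.0 - 49 * 0.002, 145.0, 50)
        tr = make_synthetic_trial(angle=angle)
        expected = np.mean(angle[-50:])
        assert final_angle(tr, segment(tr)) == pytest.approx(expected)

    def test_contracture_equilibrium_recovered(self, robot, protocol600):
        # force balance: hold_gain (145 - eq) = stiffness (eq - limit)
        limb = LimbConfig(noise_sd=0.1, contracture_limit=110.0,
                          contracture_stiffness=2.0)
        eq = (0.26 * 145.0 + 2.0 * 110.0) / (0.26 + 2.0)
        tr = filter_trial(simulate_trial(limb, robot, protocol600,
                                         "extension", 600, 65.0, 3))
        assert final_angle(tr, segment(tr)) == pytest.approx(eq, abs=0.5)


class TestCreep:
    @pytest.mark.parametrize("direction, post, fin, expected", [
        ("extension", 140.0, 143.0, 3.0),
        ("flexion", 70.0, 68.0, 2.0),
        ("extension", 120.0, 120.0, 0.0),
        ("flexion", 120.0, 120.0, 0.0),
    ])
    def test_direction_specific_formula(self, direction, post, fin, expected):
        angle = np.full(3600, post)
        angle[1700:] = fin  # settles after the post-stretch sample (1600)
        start, target = (65.0, 145.0) if direction == "extension" else (145.0, 65.0)
        tr = make_synthetic_trial(direction=direction, angle=angle,
                                  start=start, target=target)
        assert creep(tr, segment(tr)) == pytest.approx(expected)


class TestAggregation:
    @pytest.mark.parametrize("values, method, expected", [
        ([200.0, 210.0, 220.0], "mean", 210.0),
        ([210.0], "mean", 210.0),
        ([200.0, 210.0, 400.0], "median", 210.0),
    ])
    def test_methods(self, values, method, expected):
        assert aggregate_trials(values, method) == expected

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            aggregate_trials([])


class TestBetweenArmDifferences:
    @staticmethod
    def _ps(direction="extension", pv=210.0, fa=143.0, cr=0.1):
        return ParameterSet(direction=direction, duration_ms=600,
                            peak_velocity=pv, final_angle=fa, creep=cr)

    def test_self_difference_is_zero(self):
        d = between_arm_differences(self._ps(), self._ps())
        assert (d.d_peak_velocity, d.d_final_angle, d.d_creep) == (0.0, 0.0, 0.0)

    def test_signed_and_absolute_conventions(self):
        d = between_arm_differences(self._ps(pv=150.0, fa=130.0),
                                    self._ps(pv=210.0, fa=143.0))
        assert d.d_peak_velocity == 60.0
        assert d.d_final_angle == -13.0

    def test_arm_swap_symmetry(self):
        a, b = self._ps(pv=150.0, fa=130.0, cr=2.0), self._ps()
        fwd, rev = between_arm_differences(a, b), between_arm_differences(b, a)
        assert fwd.d_peak_velocity == rev.d_peak_velocity
        assert fwd.d_final_angle == -rev.d_final_angle
        assert fwd.d_creep == -rev.d_creep

    def test_direction_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            between_arm_differences(self._ps("extension"), self._ps("flexion"))


def _constructed_pair(direction, crossing_excursion=40.0, drop=60.0):
    """Reference + test trials with an analytically placed threshold crossing."""
    n = 3600
    sign = 1.0 if direction == "extension" else -1.0
    start = 65.0 if direction == "extension" else 145.0
    target = start + sign * 80.0
    rate = sign * 80.0 / 600.0  # deg per ms, linear sweep over the movement
    t = np.arange(n, dtype=float)
    angle = start + rate * np.minimum(t, 600.0)
    v_ref = np.where(t <= 600, rate * 1000.0, 0.0)
    k = int(round(crossing_excursion / (80.0 / 600.0)))  # sample of the crossing
    v_test = v_ref.copy()
    v_test[k:601] -= sign * drop
    ref = make_synthetic_trial(direction=direction, angle=angle,
                               velocity=v_ref, start=start, target=target,
                               arm="less_affected")
    test = make_synthetic_trial(direction=direction, angle=angle,
                                velocity=v_test, start=start, target=target)
    return test, ref


class TestCatchAngle:
    def test_identical_arms_yield_no_catch(self):
        _, ref = _constructed_pair("extension")
        assert catch_angle([ref], [ref], DEFAULT_VELOCITY_THRESHOLD) is None

    @pytest.mark.parametrize("direction, expected", [
        ("extension", 40.0),
        ("flexion", -40.0),
    ])
    def test_constructed_crossing_at_forty_degrees(self, direction, expected):
        test, ref = _constructed_pair(direction)
        got = catch_angle([test] * 3, [ref] * 3, DEFAULT_VELOCITY_THRESHOLD)
        assert got == pytest.approx(expected, abs=0.2)

    def test_trial_to_trial_mode_matches_on_identical_references(self):
        test, ref = _constructed_pair("extension")
        a = catch_angle([test] * 3, [ref] * 3, 50.1, mode="trial_to_mean")
        b = catch_angle([test] * 3, [ref] * 3, 50.1, mode="trial_to_trial")
        assert a == b

    def test_nonpositive_threshold_rejected(self):
        test, ref = _constructed_pair("extension")
        with pytest.raises(ParameterError):
            catch_angle([test], [ref], 0.0)

    def test_difference_trace_peak_bounds_difference_of_peaks(self):
        test, ref = _constructed_pair("extension")
        vdp = velocity_difference_peak([test] * 3, [ref] * 3)
        ps_t = single_arm_parameters([test] * 3)
        ps_r = single_arm_parameters([ref] * 3)
        d = between_arm_differences(ps_t, ps_r)
        assert vdp >= d.d_peak_velocity - 1e-9


class TestSimulatorRecovery:
    def test_catch_excursion_recovered_both_directions(self, robot, protocol600):
        rng = np.random.default_rng(7)
        for direction, sign in (("extension", 1.0), ("flexion", -1.0)):
            start = 65.0 if direction == "extension" else 145.0
            spastic = LimbConfig(spastic_gain=15.0, catch_onset_excursion=40.0)
            healthy = LimbConfig()
            tt = [filter_trial(simulate_trial(spastic, robot, protocol600,
                                              direction, 600, start, rng))
                  for _ in range(3)]
            rt = [filter_trial(simulate_trial(healthy, robot, protocol600,
                                              direction, 600, start, rng))
                  for _ in range(3)]
            got = catch_angle(tt, rt, DEFAULT_VELOCITY_THRESHOLD)
            assert got == pytest.approx(sign * 40.0, abs=3.0)

    def test_affected_peak_velocity_monotone_in_severity(self, robot,
                                                         protocol600):
        ref = LimbConfig(noise_sd=0.0)
        pv, dpv = [], []
        tr_ref = filter_trial(simulate_trial(ref, robot, protocol600,
                                             "extension", 600, 65.0, 0))
        w = segment(tr_ref)
        pv_ref = peak_velocity(tr_ref, w)
        for gain in (0.0, 3.0, 7.0, 15.0):
            limb = LimbConfig(noise_sd=0.0, spastic_gain=gain,
                              catch_onset_excursion=30.0)
            tr = filter_trial(simulate_trial(limb, robot, protocol600,
                                             "extension", 600, 65.0, 0))
            p = peak_velocity(tr, segment(tr))
            pv.append(p)
            dpv.append(abs(p - pv_ref))
        assert all(a >= b - 1e-6 for a, b in zip(pv, pv[1:]))
        assert all(b >= a - 1e-6 for a, b in zip(dpv, dpv[1:]))

    def test_creep_positive_in_both_directions_under_relaxation(
            self, robot, protocol600):
        limb = LimbConfig(spastic_gain=7.0, catch_onset_excursion=40.0,
                          release_time_constant=1.2, noise_sd=0.1)
        for direction in ("extension", "flexion"):
            start = 65.0 if direction == "extension" else 145.0
            tr = filter_trial(simulate_trial(limb, robot, protocol600,
                                             direction, 600, start, 1))
            assert creep(tr, segment(tr)) > 0.5


class TestExtraction:
    def test_cohort_table_shape_and_columns(self, protocol600):
        from kaps.config import CohortConfig

        meta, trials, _ = simulate_cohort(CohortConfig(n=3), seed=2,
                                          protocol=protocol600)
        table = extract_cohort(trials, meta)
        assert len(table) == 3
        for direction in ("flexion", "extension"):
            for p in ("peak_velocity", "final_angle", "creep",
                      "d_peak_velocity", "d_final_angle", "d_creep",
                      "catch_angle", "velocity_difference_peak"):
                assert f"{direction}_{p}" in table.columns
            assert f"{direction}_peak_velocity_trial1" in table.columns
        assert table["extension_d_peak_velocity"].ge(0).all()
        agg = table[[f"extension_peak_velocity_trial{k}" for k in (1, 2, 3)]].mean(axis=1)
        np.testing.assert_allclose(agg, table["extension_peak_velocity"])

    def test_missing_arm_rejected(self, robot, protocol600):
        tr = simulate_trial(LimbConfig(), robot, protocol600, "extension",
                            600, 65.0, 0)
        with pytest.raises(ParameterError, match="missing"):
            extract_subject([tr])
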