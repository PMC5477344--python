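"""Normative model: age regression, Box-Cox, outliers, cutoffs, z-scores."""

import numpy as np
import pandas as pd
import pytest

from kaps.errors import DegenerateDataError, ModelError
from kaps.norms import (
    NormativeModel,
    PARAMETER_TAILS,
    boxcox_normalize,
    compute_cutoffs,
    fit_age_regression,
    remove_outliers,
    velocity_difference_threshold,
    zscore,
)
from kaps.norms import test_group_effects as group_effects  # avoid pytest collection


class TestAgeRegression:
    def test_exactly_linear_values_leave_zero_residuals(self):
        ages = np.linspace(20, 80, 30)
        values = 5.0 + 0.3 * ages
        reg = fit_age_regression(values, ages)
        assert reg.slope == pytest.approx(0.3)
        adj = reg.adjust(values, ages)
        np.testing.assert_allclose(adj, adj[0] * np.ones_like(adj), atol=1e-9)

    def test_null_slope_recovered_within_two_se(self):
        rng = np.random.default_rng(4)
        ages = rng.uniform(20, 80, 96)
        values = rng.normal(100, 5, 96)
        reg = fit_age_regression(values, ages)
        from scipy.stats import linregress
        se = linregress(ages, values).stderr
        assert abs(reg.slope) < 2 * se

    def test_zero_age_variance_warns_and_skips(self):
        with pytest.warns(UserWarning, match="zero age variance"):
            reg = fit_age_regression(np.arange(12.0), np.full(12, 50.0))
        assert reg.slope == 0.0 and not reg.fitted

    def test_too_few_controls_rejected(self):
        with pytest.raises(ModelError):
            fit_age_regression([1.0, 2.0], [30.0, 40.0])


class TestBoxCox:
    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            boxcox_normalize(np.ones(50))

    def test_lognormal_sample_recovers_log_lambda(self):
        rng = np.random.default_rng(6)
        tf, _ = boxcox_normalize(np.exp(rng.normal(0, 1, 96)))
        assert -0.3 <= tf.lmbda <= 0.3

    def test_normal_sample_recovers_identity_lambda(self):
        rng = np.random.default_rng(6)
        tf, _ = boxcox_normalize(rng.normal(0, 1, 96))  # shift engages: high effective CV
        assert 0.6 <= tf.lmbda <= 1.4
        assert tf.normalizable

    def test_shift_makes_nonpositive_values_transformable(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, 96)  # straddles zero
        tf, _ = boxcox_normalize(values)
        assert tf.shift == pytest.approx(1.0 - values.min())
        round_trip = tf.inverse(tf(values))
        np.testing.assert_allclose(round_trip, values, atol=1e-8)


class TestOutlierRemoval:
    def test_clean_gaussian_cohort_loses_at_most_two(self):
        rng = np.random.default_rng(9)
        matrix = pd.DataFrame(rng.normal(0, 1, (96, 6)))
        kept, excluded = remove_outliers(matrix)
        assert len(excluded) <= 2

    def test_gross_outlier_excluded_everywhere(self):
        rng = np.random.default_rng(9)
        matrix = pd.DataFrame(rng.normal(0, 1, (96, 3)))
        matrix.iloc[7, 0] = 10.0
        kept, excluded = remove_outliers(matrix)
        assert 7 in excluded and 7 not in kept

    def test_identical_values_produce_no_exclusions(self):
        matrix = pd.DataFrame(np.full((30, 3), 4.2))
        kept, excluded = remove_outliers(matrix)
        assert excluded == [] and len(kept) == 30

    def test_mass_exclusion_refused(self):
        rng = np.random.default_rng(9)
        matrix = pd.DataFrame(rng.normal(0, 1, (96, 1)))
        matrix.iloc[:30, 0] += 100.0
        with pytest.raises(ModelError, match="refusing"):
            remove_outliers(matrix)


class TestGroupEffects:
    def test_injected_offset_detected(self):
        rng = np.random.default_rng(2)
        values = np.r_[rng.normal(0, 1, 48), rng.normal(1, 1, 48)]
        labels = np.r_[["M"] * 48, ["F"] * 48]
        assert group_effects(values, labels).significant

    def test_identical_distributions_not_flagged(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, 96)
        labels = np.r_[["M"] * 48, ["F"] * 48]
        assert not group_effects(values, labels).significant

    def test_single_group_yields_no_test(self):
        verdict = group_effects(np.arange(10.0), ["M"] * 10)
        assert not verdict.tested

    def test_tiny_group_yields_no_test(self):
        verdict = group_effects(np.arange(10.0), ["M"] * 9 + ["F"])
        assert not verdict.tested


class TestCutoffsAndThreshold:
    def test_linear_interpolation_definition(self):
        assert compute_cutoffs(np.arange(1.0, 101.0), "low") == pytest.approx(5.95)

    def test_constant_distribution_cutoff(self):
        assert compute_cutoffs(np.full(40, 3.3), "high") == pytest.approx(3.3)

    def test_normal_sample_95th_in_order_statistic_range(self):
        rng = np.random.default_rng(13)
        c = compute_cutoffs(rng.normal(0, 1, 96), "high")
        assert 1.35 <= c <= 1.95

    def test_absent_control_data_falls_back_to_published_constant(self):
        value, source = velocity_difference_threshold(None)
        assert value == 50.1 and source == "paper_default"

    def test_constant_differences_return_that_constant(self):
        value, source = velocity_difference_threshold(np.full(30, 12.5))
        assert value == pytest.approx(12.5) and source == "fitted"

    def test_half_normal_threshold_matches_analytic_quantile(self):
        rng = np.random.default_rng(3)
        scale = 4.0
        d = np.abs(rng.normal(0, scale, 20000))
        value, _ = velocity_difference_threshold(d)
        from scipy.stats import norm
        analytic = scale * norm.ppf(1 - 0.01 / 2)
        assert value == pytest.approx(analytic, rel=0.05)


def _control_table(n=96, seed=0, sex_offset=0.0, age_slope=0.0):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(20, 80, n)
    sexes = np.where(rng.random(n) < 0.5, "F", "M")
    table = {"subject_id": [f"C{i}" for i in range(n)], "age": ages,
             "sex": sexes, "handedness": ["R"] * n}
    for name in PARAMETER_TAILS:
        base = rng.normal(100, 10, n) + age_slope * (ages - 50)
        base += np.where(sexes == "M", sex_offset, 0.0)
        table[name] = base
    return pd.DataFrame(table)


class TestNormativeModelEstimator:
    def test_fit_exposes_sklearn_style_state(self):
        model = NormativeModel().fit(_control_table())
        assert set(model.parameters_) == set(PARAMETER_TAILS)
        assert model.n_controls_used_ <= 96
        assert model.get_params()["shapiro_alpha"] == 0.01

    def test_zscore_zero_at_control_mean_and_1645_at_cutoff(self):
        table = _control_table(seed=5)
        model = NormativeModel().fit(table)
        fit = model.parameters_["extension_peak_velocity"]
        mean_val = table["extension_peak_velocity"].mean()
        z_mid = fit.zscore(mean_val, age=50.0, sex="M")
        assert abs(z_mid) < 0.3
        st = fit.stratum_for("M")
        z_cut = fit.zscore(st.cutoff, age=fit.age.mean_age, sex="M")
        assert abs(abs(z_cut) - 1.645) < 0.35

    def test_back_transform_consistency(self):
        model = NormativeModel().fit(_control_table(seed=8))
        for fit in model.parameters_.values():
            for st in fit.strata.values():
                again = float(fit.transform([st.cutoff])[0])
                assert again == pytest.approx(st.cutoff_t, abs=1e-8)

    def test_sex_offset_triggers_stratification_and_equalizes_rates(self):
        train = _control_table(seed=11, sex_offset=10.0)
        model = NormativeModel().fit(train)
        fit = model.parameters_["flexion_creep"]
        assert fit.sex_effect.significant and fit.stratified
        test = _control_table(seed=12, sex_offset=10.0, )
        flags = model.classify(test)["flexion_creep"].to_numpy()
        m = (test.sex == "M").to_numpy()
        rate_m, rate_f = flags[m].mean(), flags[~m].mean()
        # pooled cutoffs on a 1-SD offset would put nearly all flags in one
        # sex; stratified cutoffs keep both rates near the nominal tail
        assert abs(rate_m - rate_f) < 0.12

    def test_nonparametric_parameter_gets_flag_but_no_z(self):
        table = _control_table(seed=3)
        rng = np.random.default_rng(0)
        # bimodal: Box-Cox cannot normalize, Shapiro gate must fail
        table["extension_creep"] = np.r_[rng.normal(0, 0.1, 48),
                                         rng.normal(10, 0.1, 48)]
        model = NormativeModel().fit(table)
        fit = model.parameters_["extension_creep"]
        assert not fit.transform.normalizable
        res = zscore(5.0, fit, age=50.0, sex="M")
        assert res.z is None and res.percentile_flag in ("impaired", "normal")

    def test_json_round_trip_preserves_decisions(self, tmp_path):
        table = _control_table(seed=21)
        model = NormativeModel().fit(table)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = NormativeModel.from_json(path)
        assert back.velocity_threshold_ == model.velocity_threshold_
        row = table.iloc[[0]]
        pd.testing.assert_frame_equal(model.transform(row), back.transform(row))
        pd.testing.assert_frame_equal(model.classify(row), back.classify(row))

    def test_missing_parameter_columns_rejected(self):
        with pytest.raises(ModelError, match="missing"):
            NormativeModel(parameters=["extension_peak_velocity"]).fit(
                pd.DataFrame({"age": np.arange(30.0)}))
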