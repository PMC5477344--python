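"""Normative model of healthy-control passive-stretch performance.

Per parameter the control pipeline is: age-regress (ordinary least
squares), Box-Cox-transform where possible (Shapiro-Wilk gate), remove
controls that are robust-z outliers on any parameter, test for sex and
handedness effects, and compute one-tailed percentile cutoffs (5th or 95th
per the parameter's impaired tail, sex-stratified when a sex effect is
found). Subjects are later compared to the cutoffs after adjusting their
value to the mean control age; z-scores are defined for parameters that
are normal or transformable to normal and oriented so that positive values
point toward the impaired tail.

:class:`NormativeModel` is a scikit-learn style estimator: ``fit`` on a
wide control table, ``transform`` to z-scores, ``predict`` failure counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import inv_boxcox
from sklearn.base import BaseEstimator

from .errors import DegenerateDataError, ModelError
from .params import DEFAULT_VELOCITY_THRESHOLD

#: Impaired tail of each parameter x direction, in this package's
#: conventions (peak velocity as magnitude, internal elbow angle in deg,
#: creep positive toward the target, differences test-arm minus reference).
#: Slower, less extended, more creep, and larger between-arm asymmetry are
#: the impaired directions.
PARAMETER_TAILS: dict[str, str] = {
    "extension_peak_velocity": "low",
    "flexion_peak_velocity": "low",
    "extension_final_angle": "low",
    "flexion_final_angle": "high",
    "extension_creep": "high",
    "flexion_creep": "high",
    "extension_d_peak_velocity": "high",
    "flexion_d_peak_velocity": "high",
    "extension_d_final_angle": "low",
    "flexion_d_final_angle": "high",
    "extension_d_creep": "high",
    "flexion_d_creep": "high",
}

CATCH_COLUMNS = ("extension_catch_angle", "flexion_catch_angle")


# ---------------------------------------------------------------------------
# building blocks


@dataclass
class AgeRegression:
    slope: float
    intercept: float
    mean_age: float
    fitted: bool

    def adjust(self, values, ages):
        """Map values to their equivalent at the mean control age."""
        values = np.asarray(values, dtype=float)
        if not self.fitted:
            return values
        ages = np.asarray(ages, dtype=float)
        return values - self.slope * (ages - self.mean_age)


def fit_age_regression(values, ages, min_n: int = 10) -> AgeRegression:
    """OLS of parameter value on age; identity adjustment when degenerate."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(values) < min_n:
        raise ModelError(f"need >= {min_n} controls for age regression")
    if np.var(ages) == 0:
        warnings.warn("zero age variance: skipping age regression", stacklevel=2)
        return AgeRegression(0.0, float(np.mean(values)), float(ages[0]), False)
    res = stats.linregress(ages, values)
    return AgeRegression(float(res.slope), float(res.intercept),
                         float(np.mean(ages)), True)


@dataclass
class BoxCoxTransform:
    lmbda: float
    shift: float
    normalizable: bool
    shapiro_p: float

    def __call__(self, values):
        values = np.asarray(values, dtype=float)
        if not self.normalizable:
            return values
        shifted = np.maximum(values + self.shift, 1e-12)
        return stats.boxcox(shifted, lmbda=self.lmbda)

    def inverse(self, transformed):
        if not self.normalizable:
            return np.asarray(transformed, dtype=float)
        return inv_boxcox(np.asarray(transformed, dtype=float), self.lmbda) - self.shift


def boxcox_normalize(values, shapiro_alpha: float = 0.01) -> tuple[BoxCoxTransform, np.ndarray]:
    """Maximum-likelihood Box-Cox with a Shapiro-Wilk normality verdict.

    Values are shifted by ``1 - min`` when not strictly positive. Returns
    the transform (flagged non-normalizable when the transformed sample
    fails Shapiro-Wilk at ``shapiro_alpha``) and the transformed values
    (the raw values when non-normalizable).
    """
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        raise DegenerateDataError("constant input cannot be normalized")
    shift = 1.0 - values.min() if values.min() <= 0 else 0.0

    # Bound the ML search to lambda in [-5, 5]: outside this range the
    # power transform over/underflows for near-constant samples whose
    # profile likelihood is flat, without improving normality.
    def _bounded(fun):
        from scipy import optimize
        return optimize.minimize_scalar(fun, bounds=(-5.0, 5.0), method="bounded")

    transformed, lmbda = stats.boxcox(values + shift, optimizer=_bounded)
    p = float(stats.shapiro(transformed).pvalue)
    tf = BoxCoxTransform(float(lmbda), float(shift), p >= shapiro_alpha, p)
    return tf, (transformed if tf.normalizable else values)


def robust_z(values) -> np.ndarray:
    """(x - median) / (1.4826 MAD), with an epsilon floor on the MAD."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    return (values - med) / max(1.4826 * mad, 1e-12)


def remove_outliers(matrix: pd.DataFrame, z_limit: float = 3.29,
                    max_fraction: float = 0.25) -> tuple[list, list]:
    """Flag rows whose robust z exceeds ``z_limit`` on any column.

    Exclusion is global: a subject flagged on one parameter is removed from
    all subsequent analyses. Refuses (raises) when more than
    ``max_fraction`` of rows would be dropped, which indicates a misfit
    rather than a few aberrant controls.
    """
    bad = pd.Series(False, index=matrix.index)
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        z = np.zeros(len(x))
        z[ok] = robust_z(x[ok])
        bad |= pd.Series(np.abs(z) > z_limit, index=matrix.index)
    excluded = list(matrix.index[bad])
    if len(excluded) > max_fraction * len(matrix):
        raise ModelError(
            f"outlier rule would remove {len(excluded)}/{len(matrix)} controls "
            f"(> {max_fraction:.0%}); refusing — check the model fit"
        )
    return list(matrix.index[~bad]), excluded


@dataclass
class GroupEffect:
    tested: bool
    p_value: float | None
    significant: bool
    test_name: str


def test_group_effects(values, labels, normalizable: bool = True,
                       alpha: float = 0.05, min_per_group: int = 5) -> GroupEffect:
    """Two-sample test for a grouping effect (t when normal, rank-sum otherwise)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) != 2 or min(len(g) for g in groups) < min_per_group:
        return GroupEffect(False, None, False, "none")
    if normalizable:
        p = float(stats.ttest_ind(groups[0], groups[1]).pvalue)
        name = "t"
    else:
        p = float(stats.mannwhitneyu(groups[0], groups[1],
                                     alternative="two-sided").pvalue)
        name = "mann-whitney"
    return GroupEffect(True, p, p < alpha, name)


def compute_cutoffs(transformed, tail: str, low: float = 5.0, high: float = 95.0
                    ) -> float:
    """One-tailed empirical percentile (linear interpolation) in transformed space."""
    transformed = np.asarray(transformed, dtype=float)
    pct = low if tail == "low" else high
    return float(np.quantile(transformed, pct / 100.0, method="linear"))


def velocity_difference_threshold(differences=None, percentile: float = 99.0
                                  ) -> tuple[float, str]:
    """99th percentile of control between-arm peak velocity differences.

    Uses the Weibull (exceedance-unbiased) quantile definition: the
    threshold exists to bound the healthy false-positive catch rate at
    1 - percentile/100, and for an extreme percentile from ~100 controls
    the plotting-position estimator h = (n+1)p keeps the expected
    exceedance at that nominal rate (the interpolated-median definition
    would double it). Falls back to the packaged reference constant
    (50.1 deg/s) with a ``"paper_default"`` provenance flag when no
    control data are supplied.
    """
    if differences is None or len(np.atleast_1d(differences)) == 0:
        return DEFAULT_VELOCITY_THRESHOLD, "paper_default"
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        return DEFAULT_VELOCITY_THRESHOLD, "paper_default"
    return float(np.quantile(d, percentile / 100.0, method="weibull")), "fitted"


# ---------------------------------------------------------------------------
# per-parameter fit


@dataclass
class StratumStats:
    n: int
    cutoff: float        # on the original (age-adjusted) scale
    cutoff_t: float      # the same cutoff in transformed space
    t_mean: float
    t_sd: float


@dataclass
class ParameterFit:
    name: str
    tail: str
    age: AgeRegression
    transform: BoxCoxTransform
    sex_effect: GroupEffect
    stratified: bool
    strata: dict = field(default_factory=dict)   # stratum label (or "all") -> StratumStats
    cutoff_percentile: float = 5.0

    def stratum_for(self, sex) -> StratumStats:
        if self.stratified:
            key = str(sex)
            if key not in self.strata:
                raise ModelError(
                    f"{self.name}: sex-stratified cutoffs need a subject sex "
                    f"in {sorted(self.strata)}, got {sex!r}"
                )
            return self.strata[key]
        return self.strata["all"]

    def adjusted(self, value: float, age: float | None) -> float:
        if age is None or not self.age.fitted:
            return float(value)
        return float(self.age.adjust([value], [age])[0])

    def zscore(self, value: float, age: float | None = None, sex=None):
        """Oriented z (positive toward the impaired tail); None when nonparametric."""
        if not self.transform.normalizable:
            return None
        st = self.stratum_for(sex)
        t = float(self.transform([self.adjusted(value, age)])[0])
        z = (t - st.t_mean) / st.t_sd
        return z if self.tail == "high" else -z

    def is_impaired(self, value: float, age: float | None = None, sex=None) -> bool:
        """Strict one-tailed comparison; values exactly at the cutoff are normal."""
        st = self.stratum_for(sex)
        adj = self.adjusted(value, age)
        return adj > st.cutoff if self.tail == "high" else adj < st.cutoff


@dataclass
class ZScoreResult:
    parameter: str
    z: float | None
    percentile_flag: str  # "impaired" | "normal"


def zscore(value: float, fit: ParameterFit, age: float | None = None,
           sex=None) -> ZScoreResult:
    """Z-score and percentile flag of one subject value under one parameter fit."""
    flag = "impaired" if fit.is_impaired(value, age, sex) else "normal"
    return ZScoreResult(fit.name, fit.zscore(value, age, sex), flag)


# ---------------------------------------------------------------------------
# the estimator


class NormativeModel(BaseEstimator):
    """Sklearn-style normative model fitted on a wide control table.

    The fit table needs one row per control with the parameter columns of
    :data:`PARAMETER_TAILS` (any subset), plus optional ``age``, ``sex``,
    ``handedness`` and between-arm peak-velocity-difference columns used
    for the catch threshold.

    Parameters
    ----------
    parameters : list of str, optional
        Parameter columns to model; defaults to every known column present.
    low_percentile, high_percentile : float
        Cutoff percentiles for low- and high-tailed parameters.
    shapiro_alpha : float
        Normality gate on Box-Cox-transformed values.
    outlier_z : float
        Robust-z magnitude beyond which a control is excluded everywhere.
    group_alpha : float
        Alpha for the sex / handedness effect tests.
    min_stratum : int
        Minimum controls per sex stratum; smaller strata fall back to
        pooled cutoffs with a warning.
    threshold_percentile : float
        Percentile of control between-arm peak velocity differences used as
        the catch velocity-difference threshold.

    Attributes (after ``fit``)
    --------------------------
    parameters_ : dict of str -> ParameterFit
    excluded_outlier_ids_ : list
    n_controls_used_ : int
    velocity_threshold_ : float
    threshold_source_ : str  ("fitted" or "paper_default")
    handedness_effects_ : dict of str -> GroupEffect
    """

    def __init__(self, parameters=None, low_percentile=5.0, high_percentile=95.0,
                 shapiro_alpha=0.01, outlier_z=3.29, max_outlier_fraction=0.25,
                 group_alpha=0.05, min_stratum=20, threshold_percentile=99.0,
                 age_col="age", sex_col="sex", handedness_col="handedness",
                 id_col="subject_id"):
        self.parameters = parameters
        self.low_percentile = low_percentile
        self.high_percentile = high_percentile
        self.shapiro_alpha = shapiro_alpha
        self.outlier_z = outlier_z
        self.max_outlier_fraction = max_outlier_fraction
        self.group_alpha = group_alpha
        self.min_stratum = min_stratum
        self.threshold_percentile = threshold_percentile
        self.age_col = age_col
        self.sex_col = sex_col
        self.handedness_col = handedness_col
        self.id_col = id_col

    # -- fitting ----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "NormativeModel":
        X = pd.DataFrame(X).reset_index(drop=True)
        names = self.parameters or [c for c in PARAMETER_TAILS if c in X.columns]
        missing = [c for c in names if c not in X.columns]
        if missing:
            raise ModelError(f"fit table is missing parameter columns: {missing}")
        if len(X) < 20:
            raise ModelError("need >= 20 controls to fit a normative model")
        ages = X[self.age_col].to_numpy(float) if self.age_col in X.columns else None
        ids = (X[self.id_col] if self.id_col in X.columns
               else pd.Series(X.index, index=X.index))

        # pass 1: preliminary transforms to express every parameter on a
        # comparable scale, then the global robust-z outlier rule
        prelim = {}
        for name in names:
            adj, _ = self._age_adjusted(X[name].to_numpy(float), ages)
            try:
                _, transformed = boxcox_normalize(adj, self.shapiro_alpha)
            except DegenerateDataError:
                transformed = adj
            prelim[name] = transformed
        kept_idx, excl_idx = remove_outliers(
            pd.DataFrame(prelim, index=X.index),
            self.outlier_z, self.max_outlier_fraction,
        )
        self.excluded_outlier_ids_ = [ids[i] for i in excl_idx]
        kept = X.loc[kept_idx].reset_index(drop=True)
        ages_kept = (kept[self.age_col].to_numpy(float)
                     if self.age_col in kept.columns else None)
        sexes = (kept[self.sex_col].astype(str).to_numpy()
                 if self.sex_col in kept.columns else None)
        hands = (kept[self.handedness_col].astype(str).to_numpy()
                 if self.handedness_col in kept.columns else None)

        # pass 2: final per-parameter fits on the kept controls
        self.parameters_ = {}
        self.handedness_effects_ = {}
        for name in names:
            fit = self._fit_parameter(
                name, kept[name].to_numpy(float), ages_kept, sexes)
            self.parameters_[name] = fit
            if hands is not None:
                self.handedness_effects_[name] = test_group_effects(
                    fit.transform(fit.age.adjust(kept[name].to_numpy(float),
                                                 ages_kept)
                                  if fit.age.fitted else kept[name].to_numpy(float)),
                    hands, fit.transform.normalizable, self.group_alpha)
        if any(e.significant for e in self.handedness_effects_.values()):
            sig = [k for k, e in self.handedness_effects_.items() if e.significant]
            warnings.warn(
                f"handedness effect detected on {sig}; cutoffs remain pooled "
                "across sides — consider side-specific handling", stacklevel=2)

        # The catch threshold bounds the per-sample velocity-difference
        # trace, so it is fitted on the control peaks of that trace when
        # available; the difference-of-peaks parameter is a lower bound on
        # it and is used only as a fallback.
        diffs = []
        trace_cols = ("extension_velocity_difference_peak",
                      "flexion_velocity_difference_peak")
        fallback_cols = ("extension_d_peak_velocity", "flexion_d_peak_velocity")
        use = trace_cols if any(c in kept.columns for c in trace_cols) else fallback_cols
        for col in use:
            if col in kept.columns:
                diffs.append(kept[col].to_numpy(float))
        self.velocity_threshold_, self.threshold_source_ = velocity_difference_threshold(
            np.concatenate(diffs) if diffs else None, self.threshold_percentile)
        self.n_controls_used_ = len(kept)
        self.n_features_in_ = len(names)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def _age_adjusted(self, values, ages):
        if ages is None:
            reg = AgeRegression(0.0, float(np.mean(values)), 0.0, False)
            return values, reg
        reg = fit_age_regression(values, ages)
        return reg.adjust(values, ages), reg

    def _fit_parameter(self, name, values, ages, sexes) -> ParameterFit:
        tail = PARAMETER_TAILS.get(name, "high")
        adj, reg = self._age_adjusted(values, ages)
        tf, transformed = boxcox_normalize(adj, self.shapiro_alpha)
        sex_effect = GroupEffect(False, None, False, "none")
        if sexes is not None:
            sex_effect = test_group_effects(
                transformed, sexes, tf.normalizable, self.group_alpha)
        pct = self.low_percentile if tail == "low" else self.high_percentile
        strata: dict[str, StratumStats] = {}
        stratified = False
        if sex_effect.significant:
            groups = {s: transformed[np.asarray(sexes) == s]
                      for s in pd.unique(np.asarray(sexes))}
            if min(len(g) for g in groups.values()) >= self.min_stratum:
                stratified = True
                for s, g in groups.items():
                    strata[str(s)] = self._stratum(g, tf, tail, pct)
            else:
                warnings.warn(
                    f"{name}: sex effect found but a stratum has fewer than "
                    f"{self.min_stratum} controls; using pooled cutoffs",
                    stacklevel=3)
        if not stratified:
            strata["all"] = self._stratum(transformed, tf, tail, pct)
        return ParameterFit(name=name, tail=tail, age=reg, transform=tf,
                            sex_effect=sex_effect, stratified=stratified,
                            strata=strata, cutoff_percentile=pct)

    @staticmethod
    def _stratum(transformed, tf: BoxCoxTransform, tail: str, pct_value: float
                 ) -> StratumStats:
        cutoff_t = compute_cutoffs(transformed, tail, pct_value, pct_value)
        return StratumStats(
            n=len(transformed),
            cutoff=float(tf.inverse(cutoff_t)),
            cutoff_t=float(cutoff_t),
            t_mean=float(np.mean(transformed)),
            t_sd=float(np.std(transformed, ddof=1)),
        )

    # -- application ------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "parameters_"):
            raise ModelError("this NormativeModel instance is not fitted yet")

    def _demographics(self, X, i):
        age = float(X[self.age_col].iloc[i]) if self.age_col in X.columns else None
        sex = str(X[self.sex_col].iloc[i]) if self.sex_col in X.columns else None
        return age, sex

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Oriented z-scores (NaN for nonparametric parameters)."""
        self._check_fitted()
        X = pd.DataFrame(X)
        out = {}
        for name, fit in self.parameters_.items():
            col = np.full(len(X), np.nan)
            for i in range(len(X)):
                age, sex = self._demographics(X, i)
                v = X[name].iloc[i]
                if np.isfinite(v):
                    z = fit.zscore(float(v), age, sex)
                    col[i] = np.nan if z is None else z
            out[name] = col
        return pd.DataFrame(out, index=X.index)

    def classify(self, X: pd.DataFrame) -> pd.DataFrame:
        """Boolean impairment flags per modelled parameter."""
        self._check_fitted()
        X = pd.DataFrame(X)
        out = {}
        for name, fit in self.parameters_.items():
            col = np.zeros(len(X), dtype=bool)
            for i in range(len(X)):
                age, sex = self._demographics(X, i)
                v = X[name].iloc[i]
                if np.isfinite(v):
                    col[i] = fit.is_impaired(float(v), age, sex)
            out[name] = col
        return pd.DataFrame(out, index=X.index)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Failure counts over the modelled parameters plus catch slots."""
        from .impairment import assess_cohort

        reports = assess_cohort(X, self)
        return np.asarray([r.failure_count for r in reports])

    # -- persistence ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        self._check_fitted()
        payload = {
            "params": self.get_params(),
            "velocity_threshold": self.velocity_threshold_,
            "threshold_source": self.threshold_source_,
            "n_controls_used": self.n_controls_used_,
            "excluded_outlier_ids": [str(s) for s in self.excluded_outlier_ids_],
            "parameters": {k: _fit_to_dict(v) for k, v in self.parameters_.items()},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NormativeModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        model = cls(**payload["params"])
        model.velocity_threshold_ = payload["velocity_threshold"]
        model.threshold_source_ = payload["threshold_source"]
        model.n_controls_used_ = payload["n_controls_used"]
        model.excluded_outlier_ids_ = payload["excluded_outlier_ids"]
        model.parameters_ = {k: _fit_from_dict(v)
                             for k, v in payload["parameters"].items()}
        model.handedness_effects_ = {}
        model.n_features_in_ = len(model.parameters_)
        model.feature_names_in_ = np.asarray(list(model.parameters_), dtype=object)
        return model


def _fit_to_dict(fit: ParameterFit) -> dict:
    d = asdict(fit)
    return d


def _fit_from_dict(d: dict) -> ParameterFit:
    return ParameterFit(
        name=d["name"], tail=d["tail"],
        age=AgeRegression(**d["age"]),
        transform=BoxCoxTransform(**d["transform"]),
        sex_effect=GroupEffect(**d["sex_effect"]),
        stratified=d["stratified"],
        strata={k: StratumStats(**v) for k, v in d["strata"].items()},
        cutoff_percentile=d["cutoff_percentile"],
    )
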