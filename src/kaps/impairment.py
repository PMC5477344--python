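"""Impairment flags, failure counts, and group summaries.

A subject fails a percentile-modelled parameter when the age-adjusted
value falls strictly beyond the parameter's one-tailed cutoff; a detected
between-arm catch counts as a failure in its own right (the detection
threshold is already the control 99th percentile, so absence is the norm).
Failure counts run over 14 slots: seven parameters in each movement
direction. Parameters that could not be computed are dropped from the
denominator and listed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ModelError
from .norms import CATCH_COLUMNS, NormativeModel, ParameterFit


def classify_parameter(value: float, fit: ParameterFit,
                       age: float | None = None, sex=None) -> str:
    """'impaired' or 'normal' by strict one-tailed comparison to the cutoff."""
    if fit.stratified and sex is None:
        raise ModelError(
            f"{fit.name}: sex-stratified cutoffs require the subject's sex")
    return "impaired" if fit.is_impaired(value, age, sex) else "normal"


@dataclass
class AssessmentReport:
    """Per-subject impairment profile."""

    subject_id: str
    flags: dict[str, bool]                 # parameter -> failed
    z_scores: dict[str, float | None]      # None for nonparametric parameters
    catch_angles: dict[str, float | None]  # catch column -> detected angle or None
    failure_count: int                     # over all available slots incl. catch
    failure_count_without_catch: int
    n_slots: int
    missing: list[str] = field(default_factory=list)
    group: str | None = None

    def __post_init__(self) -> None:
        assert self.failure_count == sum(self.flags.values()), \
            "failure_count must equal the number of impaired flags"


@dataclass
class GroupSummary:
    """Per-group failure rates and cumulative failure-count profiles."""

    failure_rates: pd.DataFrame            # group x parameter, percent impaired
    cumulative: dict[str, np.ndarray]      # group -> cumulative fraction by count
    control_boundary: float | None         # control 95th-percentile failure count


def assess_subject(row: pd.Series, model: NormativeModel, *,
                   group: str | None = None) -> AssessmentReport:
    """Assess one subject's wide parameter row against a fitted model."""
    model._check_fitted()
    age = float(row[model.age_col]) if model.age_col in row.index and \
        np.isfinite(pd.to_numeric(row.get(model.age_col), errors="coerce")) else None
    sex = str(row[model.sex_col]) if model.sex_col in row.index else None
    sid = str(row.get(model.id_col, ""))

    flags: dict[str, bool] = {}
    zs: dict[str, float | None] = {}
    missing: list[str] = []
    for name, fit in model.parameters_.items():
        v = pd.to_numeric(row.get(name), errors="coerce")
        if not np.isfinite(v):
            missing.append(name)
            continue
        flags[name] = fit.is_impaired(float(v), age, sex)
        zs[name] = fit.zscore(float(v), age, sex)
    catches: dict[str, float | None] = {}
    for col in CATCH_COLUMNS:
        if col not in row.index:
            missing.append(col)
            continue
        v = pd.to_numeric(row.get(col), errors="coerce")
        detected = bool(np.isfinite(v))
        catches[col] = float(v) if detected else None
        flags[col] = detected
    n_slots = len(flags)
    count = int(sum(flags.values()))
    count_no_catch = int(sum(v for k, v in flags.items()
                             if k not in CATCH_COLUMNS))
    return AssessmentReport(
        subject_id=sid, flags=flags, z_scores=zs, catch_angles=catches,
        failure_count=count, failure_count_without_catch=count_no_catch,
        n_slots=n_slots, missing=missing, group=group,
    )


def assess_cohort(X: pd.DataFrame, model: NormativeModel,
                  group_col: str = "group") -> list[AssessmentReport]:
    """Assess every row of a wide parameter table."""
    X = pd.DataFrame(X)
    out = []
    for i in range(len(X)):
        row = X.iloc[i]
        group = str(row[group_col]) if group_col in X.columns else None
        out.append(assess_subject(row, model, group=group))
    return out


def group_failure_rates(reports: list[AssessmentReport],
                        control_label: str = "control") -> GroupSummary:
    """Failure rates per parameter per group plus cumulative count profiles.

    The control boundary is the 95th percentile of failure counts within
    the group labelled ``control_label`` (None when absent).
    """
    if not reports:
        raise ModelError("no reports to summarize")
    by_group: dict[str, list[AssessmentReport]] = {}
    for r in reports:
        by_group.setdefault(r.group or "all", []).append(r)

    all_params = sorted({k for r in reports for k in r.flags})
    rows = {}
    cumulative: dict[str, np.ndarray] = {}
    max_slots = max(r.n_slots for r in reports)
    for g, rs in by_group.items():
        if not rs:  # pragma: no cover
            warnings.warn(f"empty group {g!r} omitted", stacklevel=2)
            continue
        rates = {}
        for p in all_params:
            have = [r.flags[p] for r in rs if p in r.flags]
            rates[p] = 100.0 * np.mean(have) if have else np.nan
        rows[g] = rates
        counts = np.asarray([r.failure_count for r in rs])
        cumulative[g] = np.asarray(
            [np.mean(counts <= k) for k in range(max_slots + 1)])
    table = pd.DataFrame(rows).T[all_params]
    boundary = None
    if control_label in by_group:
        counts = np.asarray([r.failure_count for r in by_group[control_label]])
        boundary = float(np.quantile(counts, 0.95, method="linear"))
    return GroupSummary(failure_rates=table, cumulative=cumulative,
                        control_boundary=boundary)


def report_to_dict(report: AssessmentReport) -> dict:
    """JSON-ready representation of one report (flags, z bins, catches)."""
    return {
        "subject_id": report.subject_id,
        "group": report.group,
        "flags": report.flags,
        "z_scores": report.z_scores,
        "catch_angles": report.catch_angles,
        "failure_count": report.failure_count,
        "failure_count_without_catch": report.failure_count_without_catch,
        "n_slots": report.n_slots,
        "missing": report.missing,
    }
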