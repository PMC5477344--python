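"""Reliability and validity statistics.

Inter-rater reliability uses the two-way random-effects, single-measure,
absolute-agreement intraclass correlation ICC(2,1); validity against
ordinal clinical scores uses tie-corrected Spearman rank correlation with
Bonferroni control over the family of tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ParameterError


@dataclass
class ICCResult:
    """ICC(2,1) estimate with its ANOVA mean squares."""

    icc: float
    ms_rows: float      # between-subject
    ms_cols: float      # between-rater
    ms_error: float
    n_subjects: int
    n_raters: int


def icc_absolute_agreement(rater_a, rater_b) -> ICCResult:
    """ICC(2,1): two-way random effects, single measure, absolute agreement.

    Shrout-Fleiss: (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    Absolute agreement penalises a systematic offset between raters, so a
    constant shift drives the estimate below 1.
    """
    a = np.asarray(rater_a, dtype=float)
    b = np.asarray(rater_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("rater value vectors must be 1-D and equally long")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ParameterError("missing rating pairs are not allowed")
    n = len(a)
    if n < 3:
        raise ParameterError("need ratings for at least 3 subjects")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    if ss_total == 0 or denom == 0:
        raise DegenerateDataError("zero total variance: ICC is undefined")
    return ICCResult(float((ms_rows - ms_err) / denom), float(ms_rows),
                     float(ms_cols), float(ms_err), n, k)


# ---------------------------------------------------------------------------
# Spearman with Bonferroni control


def _tie_ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return np.nan
    return float(rx @ ry) / denom


def exact_spearman_pvalue(x, y) -> float:
    """Two-sided exact permutation p-value of Spearman's rho (n <= 10).

    Enumerates all n! pairings of the (tie-averaged) ranks in chunks; ties
    are preserved because ranks, not raw values, are permuted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > 10:
        raise ParameterError("exact enumeration is limited to n <= 10")
    rx, ry = _tie_ranks(x), _tie_ranks(y)
    obs = abs(_rho_from_ranks(rx, ry))
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    if denom == 0:
        return np.nan
    count = 0
    total = 0
    chunk = 40320
    perms = itertools.permutations(range(n))
    while True:
        block = np.array(list(itertools.islice(perms, chunk)), dtype=np.intp)
        if block.size == 0:
            break
        rhos = (ryc[block] @ rxc) / denom
        count += int(np.sum(np.abs(rhos) >= obs - 1e-12))
        total += len(block)
    return count / total


def spearman_correlation(x, y, *, exact_max_n: int = 10) -> tuple[float, float]:
    """Tie-corrected Spearman rho with an exact permutation p for small n.

    Returns (rho, p). For n above ``exact_max_n`` the p-value is the
    t-approximation; constant inputs give (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    rho = float(stats.spearmanr(x, y).statistic)
    if len(x) <= exact_max_n:
        return rho, float(exact_spearman_pvalue(x, y))
    return rho, float(stats.spearmanr(x, y).pvalue)


def bonferroni_alpha(family_alpha: float = 0.05, n_tests: int = 12) -> float:
    """Per-test significance level alpha / m."""
    if n_tests < 1:
        raise ParameterError("n_tests must be >= 1")
    return family_alpha / n_tests


def spearman_with_bonferroni(parameters: pd.DataFrame, clinical: pd.DataFrame,
                             n_tests: int | None = None,
                             family_alpha: float = 0.05) -> pd.DataFrame:
    """Spearman rho of every parameter column against every clinical column.

    Rows are aligned positionally (same subjects in the same order).
    Returns a tidy table with one row per (parameter, scale) pair and a
    significance flag at the Bonferroni-corrected level; ``n_tests``
    defaults to the number of pairs actually tested.
    """
    parameters = pd.DataFrame(parameters)
    clinical = pd.DataFrame(clinical)
    if len(parameters) != len(clinical):
        raise ParameterError("parameter and clinical tables must align by row")
    if len(parameters) < 5:
        raise ParameterError("need at least 5 paired observations")
    pairs = [(p, c) for p in parameters.columns for c in clinical.columns]
    m = n_tests if n_tests is not None else len(pairs)
    alpha = bonferroni_alpha(family_alpha, m)
    rows = []
    for p, c in pairs:
        rho, pval = spearman_correlation(parameters[p], clinical[c])
        rows.append({
            "parameter": p, "scale": c, "rho": rho, "p_value": pval,
            "significant": bool(np.isfinite(pval) and pval < alpha),
            "undefined": not np.isfinite(rho),
        })
    out = pd.DataFrame(rows)
    out.attrs["corrected_alpha"] = alpha
    out.attrs["n_tests"] = m
    return out
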