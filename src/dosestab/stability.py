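"""Replicate-level stability statistics: CV, ICC(A,1) and percent difference.

Conventions follow the repeatability literature for radiomic features:

* CV = |sample SD / mean| x 100 over the k error replicates (SD with the
  n-1 denominator); undefined (NaN) when the mean is zero.
* ICC is the single-measurement, absolute-agreement, two-way random-effects
  form, ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n),
  from the two-way ANOVA mean squares with subjects as rows and raters
  (aligned replicates or fraction groups) as columns.  Its significance is
  assessed with the F test F = MSR / MSE on (n-1) and (n-1)(k-1) degrees of
  freedom, the standard companion test for this ICC form.
* PD = mean over replicates of (f_err - f_ori) / f_ori x 100, signed;
  undefined when the error-free baseline is exactly zero (such cases are
  excluded and tallied rather than silently dropped).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

CV_CATEGORIES = ("very small", "small", "intermediate", "large")


def coefficient_of_variation(values) -> float:
    """CV in percent over >= 2 replicate values; NaN when the mean is zero."""
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a flat vector of at least 2 values")
    mean = v.mean()
    if mean == 0.0:
        return np.nan
    return float(abs(v.std(ddof=1) / mean) * 100.0)


def categorize_cv(cv_percent: float) -> str:
    """Bin a CV value: <5 very small, 5-10 small, 10-20 intermediate, >=20 large."""
    if np.isnan(cv_percent):
        raise ValueError("cannot categorize an undefined CV")
    if cv_percent < 0:
        raise ValueError(f"CV must be >= 0, got {cv_percent}")
    if cv_percent < 5:
        return "very small"
    if cv_percent < 10:
        return "small"
    if cv_percent < 20:
        return "intermediate"
    return "large"


def icc_absolute_agreement(table) -> tuple[float, float]:
    """ICC(A,1) and its F-test p-value for an (n subjects x k raters) table.

    Returns (NaN, NaN) when the table has no variance at all (the agreement
    question is then undefined).
    """
    x = np.asarray(table, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("table must be 2D (subjects x raters)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("table contains missing or non-finite cells")

    grand = x.mean()
    row_mean = x.mean(axis=1)
    col_mean = x.mean(axis=0)
    ss_rows = k * np.sum((row_mean - grand) ** 2)
    ss_cols = n * np.sum((col_mean - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300 or ss_total == 0.0:
        return np.nan, np.nan
    icc = (msr - mse) / denom

    if mse == 0.0:
        p = 0.0 if msr > 0 else np.nan
    else:
        f = msr / mse
        p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


def percent_difference(f_ori: float, values) -> float:
    """Signed mean percent difference of replicates vs the error-free value.

    NaN when ``f_ori`` is exactly zero (the relative difference is undefined;
    such patients are excluded from cohort averages with an explicit tally).
    """
    v = np.asarray(values, dtype=np.float64)
    if not np.isfinite(f_ori):
        raise ValueError("f_ori must be finite")
    if f_ori == 0.0:
        return np.nan
    return float(np.mean((v - f_ori) / f_ori) * 100.0)
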