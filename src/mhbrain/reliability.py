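"""Test-retest reliability of IDPs: ICC(A,1) with adjustment variants.

ICC(A,1) is the two-way mixed-model, absolute-agreement, single-measurement
intraclass correlation (McGraw & Wong convention): it penalizes systematic
offsets between sessions, unlike consistency ICCs. Variants regress a
covariate (inter-scan interval in days, or the change in RDS-4 score) out of
each timepoint's values before the ICC, and subjects can be partitioned by
whether their RDS-4 changed between scans.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import fields as F

__all__ = ["icc_a1", "adjusted_icc", "subgroup_icc", "reliability_table",
           "modality_icc_summary"]


def _paired(scan1, scan2):
    x = np.asarray(scan1, dtype=float)
    y = np.asarray(scan2, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def icc_a1(scan1, scan2) -> float:
    """ICC(A,1): (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE)), k = 2.

    Computed from the two-way ANOVA mean squares over paired complete
    observations. Raises if fewer than 3 pairs or zero between-subject
    variance.
    """
    x, y = _paired(scan1, scan2)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if msr <= 0 or denom == 0:
        raise ValueError("zero between-subject variance: ICC undefined")
    return float((msr - mse) / denom)


def _regress_out(values, covariate):
    """Per-timepoint simple-regression residuals (intercept + covariate).

    A constant covariate is a no-op (the ICC is reported unchanged rather
    than recentred)."""
    x = np.asarray(values, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if np.ptp(c[np.isfinite(c)]) == 0:
        return x.copy()
    ok = np.isfinite(x) & np.isfinite(c)
    D = np.column_stack([np.ones(ok.sum()), c[ok]])
    beta, *_ = np.linalg.lstsq(D, x[ok], rcond=None)
    out = x.copy()
    out[ok] = x[ok] - D @ beta
    return out


def adjusted_icc(scan1, scan2, covariate, timepoints="both") -> float:
    """ICC(A,1) after regressing a per-subject covariate out of the IDP.

    ``timepoints`` selects where the regression is applied: 'both' (default),
    'first' or 'second'. A constant covariate leaves the ICC unchanged.
    """
    x = np.asarray(scan1, dtype=float)
    y = np.asarray(scan2, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if not np.isfinite(cov).all():
        raise ValueError("covariate must be complete")
    if timepoints in ("both", "first"):
        x = _regress_out(x, cov)
    if timepoints in ("both", "second"):
        y = _regress_out(y, cov)
    return icc_a1(x, y)


def subgroup_icc(scan1: pd.DataFrame, scan2: pd.DataFrame,
                 rds_change) -> pd.DataFrame:
    """Per-IDP ICC within RDS-4-change subgroups.

    Subjects are partitioned by ``|rds_change| == 0`` (stable) versus
    ``>= 1`` (changed); ICC(A,1) is computed per IDP column within each
    non-empty subgroup. Returns a tidy frame (idp, modality category,
    subgroup, n, icc).
    """
    delta = np.abs(np.asarray(rds_change, dtype=float))
    rows = []
    for label, mask in (("stable", delta == 0), ("changed", delta >= 1)):
        if mask.sum() < 3:
            warnings.warn(f"subgroup {label!r} too small; omitted")
            continue
        for col in scan1.columns:
            try:
                val = icc_a1(scan1.loc[mask, col], scan2.loc[mask, col])
            except ValueError:
                val = np.nan
            rows.append((col, F.RELIABILITY_CATEGORY[F.modality_of(col)],
                         label, int(mask.sum()), val))
    return pd.DataFrame(rows, columns=["idp", "category", "subgroup", "n",
                                       "icc"])


def reliability_table(scan1: pd.DataFrame, scan2: pd.DataFrame,
                      interval_days=None, rds_change=None) -> pd.DataFrame:
    """Per-IDP reliability with adjustment variants.

    ``scan1``/``scan2`` are row-aligned deconfounded IDP frames for the two
    timepoints. Optional covariates add columns: ``icc_interval_adj``
    (inter-scan interval regressed out of each timepoint) and
    ``icc_rds_change_adj``.
    """
    rows = []
    for col in scan1.columns:
        row = {"idp": col,
               "category": F.RELIABILITY_CATEGORY[F.modality_of(col)]}
        try:
            row["icc_a1"] = icc_a1(scan1[col], scan2[col])
        except ValueError:
            row["icc_a1"] = np.nan
        if interval_days is not None:
            row["icc_interval_adj"] = adjusted_icc(
                scan1[col], scan2[col], interval_days)
        if rds_change is not None:
            row["icc_rds_change_adj"] = adjusted_icc(
                scan1[col], scan2[col], rds_change)
        rows.append(row)
    return pd.DataFrame(rows)


def modality_icc_summary(table: pd.DataFrame,
                         value_column: str = "icc_a1") -> dict:
    """Per-category box summary of an ICC table (for figure-style output)."""
    out = {}
    for cat, sub in table.groupby("category"):
        v = sub[value_column].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        out[cat] = {"n": int(v.size), "median": float(med),
                    "mean": float(v.mean()), "q1": float(q1),
                    "q3": float(q3)}
    return out
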