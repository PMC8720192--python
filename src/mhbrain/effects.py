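"""Univariate effect sizes of selected IDPs in the confirmatory sample.

IDPs selected in the exploratory sample (Bonferroni-surviving averaged-UV
loadings) are tested in the held-out confirmatory sample only: Cohen's d by
probable depression status (deconfounded IDP values, raw binary grouping)
and Pearson's r against each continuous mental-health score, grouped by
imaging modality for box-summary reporting. No multiple-testing correction
is applied here — the confirmatory stage reports effect sizes, not
significance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import fields as F

__all__ = ["cohen_d", "effect_size_table", "modality_box_summary"]

CONTINUOUS_MEASURES = ("rds4", "phq9", "n12", "gad7")


def cohen_d(values, group) -> float:
    """Standardized mean difference: ``(mean1 - mean0) / pooled SD`` with
    (n-1)-weighted pooled variance."""
    x = np.asarray(values, dtype=float)
    g = np.asarray(group)
    ok = np.isfinite(x) & np.isin(g, (0, 1))
    x, g = x[ok], g[ok]
    x0, x1 = x[g == 0], x[g == 1]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("both groups need at least 2 members")
    s2 = (((len(x0) - 1) * x0.var(ddof=1) + (len(x1) - 1) * x1.var(ddof=1))
          / (len(x0) + len(x1) - 2))
    if s2 == 0.0:
        raise ValueError("zero pooled SD: d undefined")
    return float((x1.mean() - x0.mean()) / np.sqrt(s2))


def effect_size_table(idps: pd.DataFrame, scores: pd.DataFrame,
                      selection) -> pd.DataFrame:
    """Effect sizes of selected IDPs against each mental-health measure.

    Parameters
    ----------
    idps : deconfounded confirmatory-sample IDP values (columns = IDPs),
        row-aligned with ``scores``.
    scores : deconfounded continuous scores plus the raw binary
        ``depression_status`` column.
    selection : iterable of IDP column names (typically the
        Bonferroni-significant entries of an exploratory loading table).

    Returns one row per selected IDP with its modality tag, ``cohen_d`` and
    ``r_<measure>`` per continuous measure.
    """
    selection = list(selection)
    missing = [c for c in selection if c not in idps.columns]
    if missing:
        raise ValueError(f"selected IDPs absent from confirmatory data: "
                         f"{missing[:5]}")
    rows = []
    status = scores["depression_status"].to_numpy(dtype=float)
    for name in selection:
        x = idps[name].to_numpy(dtype=float)
        row = {"idp": name, "modality": F.modality_of(name)}
        try:
            row["cohen_d"] = cohen_d(x[np.isfinite(status)],
                                     status[np.isfinite(status)])
        except ValueError:
            row["cohen_d"] = np.nan
        for m in CONTINUOUS_MEASURES:
            y = scores[m].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            row[f"r_{m}"] = stats.pearsonr(x[ok], y[ok])[0] if ok.sum() > 2 \
                else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def modality_box_summary(table: pd.DataFrame, value_columns=None) -> dict:
    """Per-modality box summaries (quartiles, mean, median, 1.5-IQR fences)
    of absolute effect sizes, for figure-style reporting."""
    if value_columns is None:
        value_columns = [c for c in table.columns
                         if c == "cohen_d" or c.startswith("r_")]
    out = {}
    for modality, sub in table.groupby("modality"):
        out[modality] = {}
        for col in value_columns:
            v = np.abs(sub[col].to_numpy(dtype=float))
            v = v[np.isfinite(v)]
            if v.size == 0:
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            out[modality][col] = {
                "n": int(v.size), "mean": float(v.mean()),
                "median": float(med), "q1": float(q1), "q3": float(q3),
                "lower_fence": float(q1 - 1.5 * iqr),
                "upper_fence": float(q3 + 1.5 * iqr),
            }
    return out
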