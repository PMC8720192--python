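"""Summary-score computation for the five mental-health measures.

RDS-4 (recent depressive symptoms, four scan-day items coded 1-4, range
4-16), PHQ-9 (0-27), GAD-7 (0-21), N-12 neuroticism (0-12), and the binary
probable-depression status derived from lifetime-occurrence, episode-duration
and help-seeking fields. Missing or out-of-range items always propagate to a
missing score; they are never imputed, so downstream cohort filters see the
true missingness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import fields as F

__all__ = [
    "score_rds4", "score_sum_scale", "probable_depression_status",
    "late_onset_flag", "cronbach_alpha", "score_table", "SCALES",
]

#: scale -> (item fields, per-item code range, score range)
SCALES = {
    "rds4": (F.RDS4_FIELDS, (1, 4), (4, 16)),
    "phq9": (F.PHQ9_FIELDS, (0, 3), (0, 27)),
    "gad7": (F.GAD7_FIELDS, (0, 3), (0, 21)),
    "n12": (F.N12_FIELDS, (0, 1), (0, 12)),
}


def _sum_items(items, lo, hi, n_items):
    items = np.atleast_2d(np.asarray(items, dtype=float))
    if items.shape[1] != n_items:
        raise ValueError(f"expected {n_items} items, got {items.shape[1]}")
    valid = np.isfinite(items) & (items >= lo) & (items <= hi) \
        & (items == np.round(items))
    out = items.sum(axis=1)
    out[~valid.all(axis=1)] = np.nan
    return out


def score_rds4(items):
    """Sum of the four recent-depressive-symptom items (each 1-4; range 4-16).

    Any missing or out-of-range item yields a missing score.
    """
    return _sum_items(items, 1, 4, 4)


def score_sum_scale(items, scale: str):
    """Sum score for ``scale`` in {'phq9', 'gad7', 'n12', 'rds4'}."""
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    fields_, (lo, hi), _ = SCALES[scale]
    return _sum_items(items, lo, hi, len(fields_))


def probable_depression_status(ever_depressed, ever_disinterested,
                               dur_depressed, dur_disinterest,
                               seen_gp, seen_psych):
    """Binary lifetime-depression proxy.

    1 iff (ever depressed OR ever disinterested) AND (either episode lasted
    at least one week) AND (seen a GP OR a psychiatrist for nerves, anxiety,
    tension or depression). Any missing input yields a missing status.
    """
    arrs = [np.atleast_1d(np.asarray(a, dtype=float)) for a in
            (ever_depressed, ever_disinterested, dur_depressed,
             dur_disinterest, seen_gp, seen_psych)]
    ed, ei, dd, di, gp, ps = arrs
    ok = np.isfinite(ed) & np.isfinite(ei) & np.isfinite(dd) \
        & np.isfinite(di) & np.isfinite(gp) & np.isfinite(ps)
    status = (((ed == 1) | (ei == 1))
              & ((dd >= 1) | (di >= 1))
              & ((gp == 1) | (ps == 1))).astype(float)
    status[~ok] = np.nan
    return status


def late_onset_flag(age_first_episode):
    """1 iff the first depressive episode occurred at age 60 or older.

    A missing onset age gives 0 (no evidence of late onset, no exclusion).
    Negative ages are rejected.
    """
    age = np.atleast_1d(np.asarray(age_first_episode, dtype=float))
    if np.any(age[np.isfinite(age)] < 0):
        raise ValueError("negative age at first episode")
    return np.where(np.isfinite(age) & (age >= 60.0), 1, 0)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's internal-consistency alpha.

    ``alpha = k/(k-1) * (1 - sum(var_items) / var(total))`` with sample
    (n-1) variances, computed on complete rows only.
    """
    X = np.asarray(item_matrix, dtype=float)
    X = X[np.isfinite(X).all(axis=1)]
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least 2 items")
    if n < 3:
        raise ValueError("need at least 3 complete subjects")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise ValueError("zero total-score variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var))


def score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-row summary scores from a phenotype table.

    Returns a frame keyed by ``subject_id``/``timepoint`` with the four
    continuous scores, probable depression status and the late-onset flag.
    """
    out = {"subject_id": table["subject_id"].to_numpy(),
           "timepoint": table["timepoint"].to_numpy()}
    for scale, (fields_, _, _) in SCALES.items():
        missing = [f_ for f_ in fields_ if f_ not in table.columns]
        if missing:
            raise ValueError(f"missing item columns for {scale}: {missing}")
        out[scale] = score_sum_scale(table[list(fields_)].to_numpy(), scale)
    out["depression_status"] = probable_depression_status(
        table[F.EVER_DEPRESSED_FIELD], table[F.EVER_DISINTERESTED_FIELD],
        table[F.DUR_DEPRESSED_FIELD], table[F.DUR_DISINTEREST_FIELD],
        table[F.SEEN_GP_FIELD], table[F.SEEN_PSYCH_FIELD])
    if F.AGE_FIRST_EPISODE_FIELD in table.columns:
        out["late_onset_flag"] = late_onset_flag(
            table[F.AGE_FIRST_EPISODE_FIELD])
    else:
        out["late_onset_flag"] = 0
    return pd.DataFrame(out)
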