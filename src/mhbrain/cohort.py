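"""Subject flow: exclusions, matched case/control pairing, sample splits.

Mirrors the standard population-imaging inclusion chart: subjects with high
scanner head motion, missing mental-health data or probable late-onset
depression are excluded; subjects scanned twice form the test-retest sample;
each remaining "ever seen GP for mental health" case is paired with a
"never seen GP" control identically matched for sex and integer age with
minimal head-motion difference; pairs are then randomly split into
exploratory and confirmatory samples.
"""

from __future__ import annotations

import io
import warnings

import numpy as np
import pandas as pd

from . import fields as F

__all__ = ["apply_exclusions", "match_pairs", "split_samples",
           "build_cohort", "flow_report"]

MOTION_THRESHOLD_MM = 0.2

#: mental-health measures that must be complete for inclusion
_MH_COLUMNS = ("rds4", "phq9", "gad7", "n12", "depression_status")


def apply_exclusions(table: pd.DataFrame, scores: pd.DataFrame,
                     motion_threshold: float = MOTION_THRESHOLD_MM
                     ) -> pd.DataFrame:
    """Flag excluded subjects, in inclusion-chart order.

    Order of precedence: head motion strictly above ``motion_threshold`` mm
    (mean resting-state motion), then any missing mental-health measure,
    then probable late-onset depression. Operates on timepoint-1 rows.

    Returns a frame with ``subject_id`` and ``exclusion_reason`` in
    {'motion', 'missing_mh', 'late_onset', 'none'}.
    """
    if "head_motion_rest" not in table.columns:
        raise ValueError("motion column 'head_motion_rest' missing")
    t1 = table[table["timepoint"] == 1]
    s1 = scores[scores["timepoint"] == 1].set_index("subject_id")
    s1 = s1.loc[t1["subject_id"].to_numpy()]

    motion = t1["head_motion_rest"].to_numpy() > motion_threshold
    missing_mh = ~np.isfinite(
        s1[list(_MH_COLUMNS)].to_numpy(dtype=float)).all(axis=1)
    late = s1["late_onset_flag"].to_numpy() == 1

    reason = np.full(len(t1), "none", dtype=object)
    reason[late] = "late_onset"
    reason[missing_mh] = "missing_mh"
    reason[motion] = "motion"          # highest precedence, applied last
    return pd.DataFrame({"subject_id": t1["subject_id"].to_numpy(),
                         "exclusion_reason": reason})


def match_pairs(cases: pd.DataFrame, controls: pd.DataFrame,
                seed: int = 0, age_tolerance: int = 0) -> pd.DataFrame:
    """Greedy 1:1 matching of cases to controls on sex and age.

    Cases are processed in seeded random order. Candidate controls must
    match sex exactly and integer age within ``age_tolerance`` years
    (default: identical). Among candidates, the control minimizing the
    absolute head-motion difference is taken and removed from the pool;
    ties break on the smallest subject id. Cases without candidates are
    returned unmatched.

    Both inputs need columns subject_id, sex, age, head_motion_rest.

    Returns a frame (case_id, control_id, pair_id); unmatched cases have
    control_id = None and no pair_id.
    """
    for df, name in ((cases, "cases"), (controls, "controls")):
        need = {"subject_id", "sex", "age", "head_motion_rest"}
        if not need.issubset(df.columns):
            raise ValueError(f"{name} missing columns {need - set(df.columns)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))

    pool = controls.copy()
    if len(pool) == 0:
        warnings.warn("empty control pool: every case is unmatched")
        pool["_age"] = pd.Series([], dtype=int)
    else:
        pool["_age"] = pool["age"].round().astype(int)
    pool = pool.sort_values("subject_id").reset_index(drop=True)
    available = np.ones(len(pool), dtype=bool)
    pool_sex = pool["sex"].to_numpy()
    pool_age = pool["_age"].to_numpy()
    pool_motion = pool["head_motion_rest"].to_numpy()
    pool_id = pool["subject_id"].to_numpy()

    rows = []
    pair_counter = 0
    c_sex = cases["sex"].to_numpy()
    c_age = cases["age"].round().astype(int).to_numpy()
    c_motion = cases["head_motion_rest"].to_numpy()
    c_id = cases["subject_id"].to_numpy()
    for i in order:
        cand = available & (pool_sex == c_sex[i]) \
            & (np.abs(pool_age - c_age[i]) <= age_tolerance)
        idx = np.nonzero(cand)[0]
        if idx.size == 0:
            rows.append((c_id[i], None, None))
            continue
        delta = np.abs(pool_motion[idx] - c_motion[i])
        # ties on |delta motion| break on smallest subject_id; the pool is
        # sorted by id so argmin on the first minimal delta suffices
        j = idx[np.argmin(delta)]
        available[j] = False
        rows.append((c_id[i], pool_id[j], f"P{pair_counter:05d}"))
        pair_counter += 1
    out = pd.DataFrame(rows, columns=["case_id", "control_id", "pair_id"])
    return out.sort_values("case_id").reset_index(drop=True)


def split_samples(pairs: pd.DataFrame, frac_exploratory: float = 2 / 3,
                  seed: int = 0) -> pd.DataFrame:
    """Randomly assign matched pairs to exploratory/confirmatory samples.

    The split is at pair level (both members stay together), taking
    ``floor(frac_exploratory * n_pairs)`` pairs for the exploratory sample.
    """
    if not (0.0 < frac_exploratory < 1.0):
        raise ValueError("frac_exploratory must be in (0, 1)")
    matched = pairs[pairs["control_id"].notna()].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(matched))
    n_exp = int(np.floor(frac_exploratory * len(matched)))
    group = np.full(len(matched), "confirmatory", dtype=object)
    group[order[:n_exp]] = "exploratory"
    out = matched.copy()
    out["group"] = group
    return out


def build_cohort(table: pd.DataFrame, scores: pd.DataFrame, seed: int = 0,
                 frac_exploratory: float = 2 / 3,
                 motion_threshold: float = MOTION_THRESHOLD_MM,
                 age_tolerance: int = 0) -> pd.DataFrame:
    """Full subject-flow: exclusions -> retest -> matching -> split.

    Returns a per-subject assignment frame with columns subject_id, group
    in {exploratory, confirmatory, retest, excluded}, pair_id and
    exclusion_reason in {motion, missing_mh, late_onset, unmatched, none}.
    Retest subjects (scanned at both timepoints) are kept out of the
    matched split, mirroring the inclusion chart.
    """
    excl = apply_exclusions(table, scores, motion_threshold)
    t1 = table[table["timepoint"] == 1].set_index("subject_id")
    retest_ids = set(table.loc[table["timepoint"] == 2, "subject_id"])

    assign = excl.set_index("subject_id")
    assign["group"] = "excluded"
    assign["pair_id"] = None
    retained = assign[assign["exclusion_reason"] == "none"].index
    is_retest = assign.index.isin(retest_ids) \
        & (assign["exclusion_reason"] == "none")
    assign.loc[is_retest, "group"] = "retest"

    elig = [s for s in retained if s not in retest_ids]
    sub = t1.loc[elig]
    seen_gp = sub[F.SEEN_GP_FIELD] == 1
    cases = sub[seen_gp].reset_index()[
        ["subject_id", "sex", "age", "head_motion_rest"]]
    controls = sub[~seen_gp].reset_index()[
        ["subject_id", "sex", "age", "head_motion_rest"]]
    pairs = match_pairs(cases, controls, seed=seed,
                        age_tolerance=age_tolerance)
    split = split_samples(pairs, frac_exploratory, seed=seed + 1)

    unmatched = pairs.loc[pairs["control_id"].isna(), "case_id"]
    assign.loc[unmatched, "exclusion_reason"] = "unmatched"
    matched_controls = set(split["control_id"])
    never_used = [s for s in controls["subject_id"]
                  if s not in matched_controls]
    assign.loc[never_used, "exclusion_reason"] = "unmatched"

    for _, row in split.iterrows():
        for member in (row["case_id"], row["control_id"]):
            assign.loc[member, "group"] = row["group"]
            assign.loc[member, "pair_id"] = row["pair_id"]
    assign.loc[assign["exclusion_reason"] != "none", "group"] = "excluded"
    return assign.reset_index()[
        ["subject_id", "group", "pair_id", "exclusion_reason"]]


def flow_report(assignment: pd.DataFrame) -> str:
    """Human-readable inclusion-chart summary of a cohort assignment."""
    buf = io.StringIO()
    n = len(assignment)
    reasons = assignment["exclusion_reason"].value_counts()
    groups = assignment["group"].value_counts()
    print(f"subjects with imaging data: {n}", file=buf)
    for reason, label in (("motion", "head motion > threshold"),
                          ("missing_mh", "missing mental-health data"),
                          ("late_onset", "probable late-onset depression"),
                          ("unmatched", "no exact sex/age match")):
        print(f"  excluded, {label}: {reasons.get(reason, 0)}", file=buf)
    for g in ("retest", "exploratory", "confirmatory"):
        print(f"assigned {g}: {groups.get(g, 0)}", file=buf)
    n_pairs = assignment["pair_id"].notna().sum() // 2
    print(f"matched case/control pairs: {n_pairs}", file=buf)
    return buf.getvalue()
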