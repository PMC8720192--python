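"""Synthetic cohort generator with a planted brain-behavior mode.

The generator emulates the statistical structure of a population-imaging
mental-health study so that every downstream stage (scoring, matched cohort
construction, confound-aware PCA->CCA, replication, effect sizes, test-retest
reliability, equipercentile linking) can be exercised and validated without
restricted data.

Generative model
----------------
A per-subject latent affect factor ``z ~ N(0, 1)`` drives

* ordinal questionnaire items through a graded threshold model: the item
  propensity is ``lam * z_eff + sqrt(1 - lam^2) * e`` cut at normal quantiles
  of right-skewed marginal level probabilities. Scan-day scales (RDS-4, N-12)
  see the scan-day affect state; online scales (PHQ-9, GAD-7) see a state
  ``z_online`` whose correlation with ``z`` decays with the questionnaire
  latency, emulating the scan-to-online timing gap;
* a low-rank component of the IDP block. IDPs have a within-modality factor
  structure (a handful of shared factors per modality plus unique noise) and
  the affect signal enters through those factors, so that modality-wise PCA
  retains it. The signal scale is calibrated such that the *population*
  canonical correlation between the IDP block and the five summary scores
  equals ``effect_r`` exactly (see :func:`_solve_signal_scale`);
* probable-depression input fields and GP help-seeking, so the matched
  case/control construction has a realistic case prevalence.

Confound effects (site, age, sex, head size, motion, date) are added to the
IDPs with known coefficients. A retest subset receives a second timepoint
whose IDPs share a stable subject component sized so that the test-retest
correlation per modality equals ``reliability_per_modality``.
"""

from __future__ import annotations

import dataclasses
import functools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import norm

from . import fields as F

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_cohort",
    "simulate_survey_retest",
    "write_phenotypes",
    "read_phenotypes",
]

# Fixed stream for model constants that must be identical across user seeds
# (score-block calibration sample, confound coefficients).
_CALIBRATION_SEED = 987_654_321

DEFAULT_IDP_COUNTS = {
    "amplitude": 8, "full-edge": 28, "partial-edge": 28,
    "volume": 14, "area": 10, "thickness": 10,
    "FA": 8, "MD": 8, "T2star": 4, "WMH": 1,
    "task": 7,
}  # 126 columns, mirroring a 126-variable brain block

#: Two-year test-retest targets: structure above function, task lowest.
DEFAULT_RELIABILITY = {
    "amplitude": 0.55, "full-edge": 0.50, "partial-edge": 0.45,
    "volume": 0.85, "area": 0.85, "thickness": 0.75,
    "FA": 0.75, "MD": 0.70, "T2star": 0.70, "WMH": 0.80,
    "task": 0.35,
}

# Graded-response item models: (fields, level codes, level probabilities,
# loading of the item propensity on the affect state, timing of acquisition).
_ITEM_MODELS = {
    "rds4": (F.RDS4_FIELDS, (1, 2, 3, 4), (0.55, 0.25, 0.12, 0.08), 0.80, "scan"),
    "phq9": (F.PHQ9_FIELDS, (0, 1, 2, 3), (0.65, 0.20, 0.10, 0.05), 0.75, "online"),
    "gad7": (F.GAD7_FIELDS, (0, 1, 2, 3), (0.65, 0.20, 0.10, 0.05), 0.75, "online"),
    "n12": (F.N12_FIELDS, (0, 1), (0.70, 0.30), 0.65, "scan"),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Parameters
    ----------
    n_subjects : number of subjects at timepoint 1.
    seed : RNG seed; a fixed seed reproduces the table bit-identically.
    effect_r : planted population canonical correlation between the IDP
        block and the five-score block, in ``[0, 1)``.
    n_idp_per_modality : IDP count per modality tag.
    reliability_per_modality : target two-year test-retest correlation of
        the deconfounded IDPs, per modality, in ``[0, 1]``.
    frac_retest : fraction of subjects receiving a second scan timepoint.
    missing_rate : MCAR rate for structural/task IDP cells; positions are
        shared across timepoints.
    latency_days_range : interval the signed online-questionnaire latency is
        drawn from (uniform, integer days).
    effect_weight_per_modality : relative strength of the planted mode per
        modality (default: equal weights).
    factor_variance_share : share of each IDP's variance carried by its
        modality factor (controls within-modality correlation).
    affect_stability : correlation between the scan-day affect states of the
        two scan timepoints (~2 years apart).
    latency_floor, latency_tau_days : the scan-day/online affect correlation
        is ``floor + (1 - floor) * exp(-|latency| / tau)``.
    frac_missing_online : fraction of subjects whose online questionnaire is
        entirely missing (they never completed it).
    scale_specific_share : variance share of a stable scale-specific factor
        in each questionnaire's effective affect state, keeping cross-scale
        score correlations below within-scale consistency.
    """

    n_subjects: int = 4000
    seed: int = 0
    effect_r: float = 0.3
    n_idp_per_modality: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_IDP_COUNTS))
    reliability_per_modality: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RELIABILITY))
    frac_retest: float = 0.15
    missing_rate: float = 0.01
    latency_days_range: tuple[int, int] = (-1185, 964)
    effect_weight_per_modality: Mapping[str, float] | None = None
    factor_variance_share: float = 0.5
    n_sites: int = 3
    affect_stability: float = 0.6
    latency_floor: float = 0.7
    latency_tau_days: float = 600.0
    frac_missing_online: float = 0.0
    scale_specific_share: float = 0.3

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0.0 <= self.effect_r < 1.0):
            raise ValueError("effect_r must be in [0, 1)")
        for name in ("frac_retest", "missing_rate", "frac_missing_online"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 < self.factor_variance_share < 1.0):
            raise ValueError("factor_variance_share must be in (0, 1)")
        if not (0.0 <= self.scale_specific_share < 1.0):
            raise ValueError("scale_specific_share must be in [0, 1)")
        for m, k in self.n_idp_per_modality.items():
            if m not in F.MODALITIES:
                raise ValueError(f"unknown modality {m!r}")
            if k < 1:
                raise ValueError(f"n_idp_per_modality[{m!r}] must be >= 1")
        for m, r in self.reliability_per_modality.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"reliability_per_modality[{m!r}] not in [0, 1]")
        lo, hi = self.latency_days_range
        if lo > hi:
            raise ValueError("latency_days_range must be (lo, hi) with lo <= hi")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_idp_per_modality"] = dict(self.n_idp_per_modality)
        d["reliability_per_modality"] = dict(self.reliability_per_modality)
        d["latency_days_range"] = list(self.latency_days_range)
        if self.effect_weight_per_modality is not None:
            d["effect_weight_per_modality"] = dict(self.effect_weight_per_modality)
        return d


@dataclass
class SimTruth:
    """Planted quantities, for validation against the generator's own oracle."""

    z: np.ndarray                 # scan-day affect state, timepoint 1
    z2: np.ndarray                # scan-day affect state, timepoint 2
    z_online: np.ndarray
    rho_y: float                  # max corr(linear combo of scores, z)
    rho_x: float                  # planted max corr(linear combo of IDPs, z)
    signal_scale: float           # alpha: z -> factor loading scale
    idp_columns: list[str]
    factor_of_idp: np.ndarray     # factor index per IDP column
    factor_modality: list[str]
    factor_signal: np.ndarray     # a_f = corr(factor_f, z)
    factor_loading: float         # l = sqrt(factor_variance_share)
    stable_share: np.ndarray      # lambda_f per factor (noise stability)
    confound_betas: np.ndarray    # (n_confound_regressors, n_idps)
    retest_ids: np.ndarray        # subject indices with a second timepoint


# --------------------------------------------------------------------------
# calibration: score-block alignment with the latent affect state
# --------------------------------------------------------------------------

def _simulate_items(rng, z_eff, model_key):
    """Ordinal item matrix for one scale given the effective affect state."""
    fields_, codes, probs, lam, _ = _ITEM_MODELS[model_key]
    cuts = norm.ppf(np.cumsum(probs)[:-1])
    prop = lam * z_eff[:, None] + np.sqrt(1.0 - lam ** 2) * \
        rng.standard_normal((len(z_eff), len(fields_)))
    idx = np.searchsorted(cuts, prop, side="left")  # 0..n_levels-1
    return np.asarray(codes)[idx]


def _simulate_depression_fields(rng, z):
    """Binary/duration fields feeding the probable-depression rule."""
    n = len(z)
    ever_dep = (rng.random(n) < norm.cdf(0.9 * z - 0.8)).astype(int)
    ever_dis = (rng.random(n) < norm.cdf(0.9 * z - 1.0)).astype(int)
    dur_dep = ever_dep * (rng.geometric(0.3, n) - 1)      # weeks, can be 0
    dur_dis = ever_dis * (rng.geometric(0.3, n) - 1)
    seen_gp = (rng.random(n) < norm.cdf(0.8 * z - 0.55)).astype(int)
    seen_psych = (rng.random(n) < norm.cdf(0.8 * z - 1.6)).astype(int)
    return ever_dep, ever_dis, dur_dep, dur_dis, seen_gp, seen_psych


def _latency_weight(latency_days, floor, tau):
    return floor + (1.0 - floor) * np.exp(-np.abs(latency_days) / tau)


def _scale_states(rng, z, z_online, s_share):
    """Per-scale effective affect state: common (timing-appropriate) affect
    plus a stable scale-specific factor, drawn in fixed scale order."""
    states, specifics = {}, {}
    for key in ("rds4", "phq9", "gad7", "n12"):
        base = z_online if _ITEM_MODELS[key][4] == "online" else z
        u = rng.standard_normal(len(base))
        specifics[key] = u
        states[key] = (np.sqrt(1.0 - s_share) * base
                       + np.sqrt(s_share) * u)
    return states, specifics


def _score_block(rng, z, z_online, s_share):
    """Summary-score matrix (rds4, phq9, gad7, n12, depression_status)."""
    states, _ = _scale_states(rng, z, z_online, s_share)
    cols = []
    for key in ("rds4", "phq9", "gad7", "n12"):
        cols.append(_simulate_items(rng, states[key], key).sum(axis=1))
    ever_dep, ever_dis, dur_dep, dur_dis, seen_gp, seen_psych = \
        _simulate_depression_fields(rng, z)
    status = (
        ((ever_dep == 1) | (ever_dis == 1))
        & ((dur_dep >= 1) | (dur_dis >= 1))
        & ((seen_gp == 1) | (seen_psych == 1))
    ).astype(int)
    cols.append(status)
    return np.column_stack(cols)


@functools.lru_cache(maxsize=8)
def _score_block_alignment(latency_range, floor, tau, s_share,
                           n_cal=100_000):
    """Population ``rho_y``: the best linear combination of the five summary
    scores achieves this correlation with the latent affect state.

    Estimated once from a large calibration sample drawn with a fixed internal
    seed, so the planted scaling is identical across user seeds.
    """
    rng = np.random.default_rng(_CALIBRATION_SEED)
    z = rng.standard_normal(n_cal)
    lat = rng.integers(latency_range[0], latency_range[1] + 1, n_cal)
    w = _latency_weight(lat, floor, tau)
    z_online = w * z + np.sqrt(1.0 - w ** 2) * rng.standard_normal(n_cal)
    Y = _score_block(rng, z, z_online, s_share).astype(float)
    Yc = Y - Y.mean(axis=0)
    S = Yc.T @ Yc / (n_cal - 1)
    c = Yc.T @ (z - z.mean()) / (n_cal - 1)
    rho2 = float(c @ np.linalg.solve(S, c))
    return float(np.sqrt(rho2))


# --------------------------------------------------------------------------
# IDP block layout and signal calibration
# --------------------------------------------------------------------------

def _idp_layout(config: SimConfig):
    """Column names, factor assignment and per-factor IDP counts."""
    columns, factor_of_idp, factor_modality, factor_sizes = [], [], [], []
    for modality in F.MODALITIES:
        n_m = config.n_idp_per_modality.get(modality, 0)
        if n_m == 0:
            continue
        k_m = max(1, n_m // 8)
        base = len(factor_modality)
        factor_modality.extend([modality] * k_m)
        sizes = np.zeros(k_m, dtype=int)
        for j in range(n_m):
            columns.append(f"idp_{modality}_{j:04d}")
            factor_of_idp.append(base + j % k_m)
            sizes[j % k_m] += 1
        factor_sizes.extend(sizes.tolist())
    return (columns, np.asarray(factor_of_idp),
            factor_modality, np.asarray(factor_sizes))


def _solve_signal_scale(config: SimConfig, rho_x, c0, factor_sizes):
    """Scale ``alpha`` such that the best linear readout of the IDP block
    attains correlation ``rho_x`` with the affect state.

    With factor signal ``a_f = alpha * c0_f``, factor loading ``l`` and
    ``n_f`` IDPs per factor, the Fisher information about ``z`` in the block
    is ``t = sum_f (a_f l)^2 n_f / ((1 - l^2) + n_f l^2 (1 - a_f^2))`` and
    ``rho_x^2 = t / (1 + t)``.
    """
    if rho_x == 0.0:
        return 0.0
    l2 = config.factor_variance_share

    def info(alpha):
        a2 = (alpha * c0) ** 2
        return float(np.sum(
            a2 * l2 * factor_sizes
            / ((1.0 - l2) + factor_sizes * l2 * (1.0 - a2))))

    t_target = rho_x ** 2 / (1.0 - rho_x ** 2)
    alpha_hi = 0.999999 / np.max(np.abs(c0))
    if info(alpha_hi) < t_target:
        raise ValueError(
            f"effect_r={config.effect_r} cannot be realized: the IDP block "
            f"supports at most rho_x={np.sqrt(info(alpha_hi) / (1 + info(alpha_hi))):.3f} "
            f"against the required {rho_x:.3f}")
    return float(brentq(lambda a: info(a) - t_target, 0.0, alpha_hi,
                        xtol=1e-12))


def _confound_design_for_effects(site, age, sex, head_size, m_rest, m_task,
                                 date, n_sites):
    """Nominal-scale confound regressors used to inject known effects."""
    cols = [(site == s).astype(float) for s in range(1, n_sites)]
    cols += [
        (age - 62.0) / 10.0,
        sex - 0.5,
        (head_size - 1.0) / 0.08,
        (m_rest - 0.12) / 0.04,
        (m_task - 0.12) / 0.04,
        (date - 750.0) / 433.0,
    ]
    return np.column_stack(cols)


# --------------------------------------------------------------------------
# main generator
# --------------------------------------------------------------------------

def simulate_cohort(config: SimConfig, return_truth: bool = False):
    """Generate a two-timepoint phenotype table with the planted structure.

    Returns a tidy table with one row per subject x timepoint holding item
    responses (columns named by UKB field ID), confounds, latency and IDP
    columns. With ``return_truth=True`` also returns a :class:`SimTruth`
    carrying every planted quantity for oracle-based validation.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    columns, factor_of_idp, factor_modality, factor_sizes = _idp_layout(cfg)
    n_idp, n_fac = len(columns), len(factor_modality)
    l = float(np.sqrt(cfg.factor_variance_share))

    # per-factor signal direction: modality effect weight split across factors
    weights = cfg.effect_weight_per_modality or {}
    c0 = np.array([
        weights.get(m, 1.0) / np.sqrt(factor_modality.count(m))
        for m in factor_modality])

    rho_y = _score_block_alignment(tuple(cfg.latency_days_range),
                                   cfg.latency_floor, cfg.latency_tau_days,
                                   cfg.scale_specific_share)
    if cfg.effect_r > 0 and cfg.effect_r >= rho_y:
        raise ValueError(
            f"effect_r={cfg.effect_r} cannot be realized: the score block is "
            f"aligned with the affect state at rho_y={rho_y:.3f} < effect_r")
    rho_x = cfg.effect_r / rho_y if cfg.effect_r > 0 else 0.0
    alpha = _solve_signal_scale(cfg, rho_x, c0, factor_sizes)
    a_f = alpha * c0                       # corr(factor_f, z)

    # stable share of the non-signal variance, per factor, such that the
    # test-retest correlation of each deconfounded IDP equals its target
    rel = np.array([cfg.reliability_per_modality.get(m, 0.6)
                    for m in factor_modality])
    sig_var = (a_f * l) ** 2               # stable-by-construction part
    if np.any(rel < sig_var - 1e-12):
        bad = [factor_modality[i] for i in np.nonzero(rel < sig_var)[0]]
        raise ValueError(
            f"reliability target below the planted signal share for {bad}; "
            "effect_r and reliability_per_modality are jointly unrealizable")
    lam_f = np.clip((rel - sig_var) / (1.0 - sig_var), 0.0, 1.0)

    # ---- subjects ---------------------------------------------------------
    z = rng.standard_normal(n)
    site = rng.integers(0, cfg.n_sites, n)
    age = rng.integers(45, 81, n).astype(float)
    sex = rng.integers(0, 2, n).astype(float)
    head_size = rng.normal(1.0, 0.08, n)
    m_rest = np.exp(rng.normal(np.log(0.115), 0.30, n))
    m_task = np.exp(rng.normal(np.log(0.115), 0.30, n))
    scan_date = rng.integers(0, 1500, n).astype(float)
    latency = rng.integers(cfg.latency_days_range[0],
                           cfg.latency_days_range[1] + 1, n).astype(float)
    w = _latency_weight(latency, cfg.latency_floor, cfg.latency_tau_days)
    z_online = w * z + np.sqrt(1.0 - w ** 2) * rng.standard_normal(n)

    # ---- items and depression fields (timepoint 1) ------------------------
    states, specifics = _scale_states(rng, z, z_online,
                                      cfg.scale_specific_share)
    items = {}
    for key in ("rds4", "phq9", "gad7", "n12"):
        mat = _simulate_items(rng, states[key], key)
        for j, f_ in enumerate(_ITEM_MODELS[key][0]):
            items[f_] = mat[:, j].astype(float)
    ever_dep, ever_dis, dur_dep, dur_dis, seen_gp, seen_psych = \
        _simulate_depression_fields(rng, z)
    age_onset = np.full(n, np.nan)
    mask_dep = ever_dep == 1
    age_onset[mask_dep] = np.minimum(
        15.0 + rng.exponential(15.0, int(mask_dep.sum())), 75.0).round()

    # ---- IDPs -------------------------------------------------------------
    eta_stable = rng.standard_normal((n, n_fac))
    u_stable = rng.standard_normal((n, n_idp))
    beta_rng = np.random.default_rng(_CALIBRATION_SEED + 1)
    n_creg = (cfg.n_sites - 1) + 6
    betas = beta_rng.normal(0.0, 0.075, (n_creg, n_idp))

    def idp_matrix(rng, z_t, site, age, sex, head_size, m_rest, m_task, date):
        eta_t = (np.sqrt(lam_f) * eta_stable
                 + np.sqrt(1.0 - lam_f) * rng.standard_normal((n, n_fac)))
        factors = a_f * z_t[:, None] + np.sqrt(1.0 - a_f ** 2) * eta_t
        u_t = (np.sqrt(lam_f[factor_of_idp]) * u_stable
               + np.sqrt(1.0 - lam_f[factor_of_idp])
               * rng.standard_normal((n, n_idp)))
        X = l * factors[:, factor_of_idp] + np.sqrt(1.0 - l ** 2) * u_t
        C = _confound_design_for_effects(site, age, sex, head_size,
                                         m_rest, m_task, date, cfg.n_sites)
        return X + C @ betas

    # the brain mode tracks the (trait-like) timepoint-1 affect state at
    # both scans; scan-day questionnaire states evolve between timepoints
    X1 = idp_matrix(rng, z, site, age, sex, head_size, m_rest, m_task,
                    scan_date)

    # ---- retest subset and timepoint 2 ------------------------------------
    n_retest = int(round(cfg.frac_retest * n))
    retest_ids = np.sort(rng.choice(n, size=n_retest, replace=False))
    z2 = (cfg.affect_stability * z
          + np.sqrt(1.0 - cfg.affect_stability ** 2) * rng.standard_normal(n))
    interval = np.clip(rng.normal(824.0, 45.0, n), 700.0, 1000.0).round()
    m_rest2 = np.exp(rng.normal(np.log(0.115), 0.30, n))
    m_task2 = np.exp(rng.normal(np.log(0.115), 0.30, n))
    age2 = age + 2.0
    date2 = scan_date + interval
    items2 = {}
    s_sh = cfg.scale_specific_share
    for key in ("rds4", "n12"):
        z_eff2 = (np.sqrt(1.0 - s_sh) * z2
                  + np.sqrt(s_sh) * specifics[key])
        mat = _simulate_items(rng, z_eff2, key)
        for j, f_ in enumerate(_ITEM_MODELS[key][0]):
            items2[f_] = mat[:, j].astype(float)
    X2 = idp_matrix(rng, z, site, age2, sex, head_size, m_rest2, m_task2,
                    date2)

    # ---- missingness (MCAR, timepoint-independent positions) --------------
    st_cols = [j for j, c in enumerate(columns)
               if F.GROUP_OF_MODALITY[F.modality_of(c)] in ("structural", "task")]
    if cfg.missing_rate > 0 and st_cols:
        hole = rng.random((n, len(st_cols))) < cfg.missing_rate
        for k, j in enumerate(st_cols):
            X1[hole[:, k], j] = np.nan
            X2[hole[:, k], j] = np.nan

    online_missing = np.zeros(n, dtype=bool)
    if cfg.frac_missing_online > 0:
        online_missing = rng.random(n) < cfg.frac_missing_online

    # ---- assemble ---------------------------------------------------------
    sid = np.array([f"S{i:06d}" for i in range(n)])
    r = retest_ids

    d1 = {"subject_id": sid, "timepoint": 1}
    for f_, v in items.items():
        vv = v.copy()
        if f_ in F.PHQ9_FIELDS or f_ in F.GAD7_FIELDS:
            vv[online_missing] = np.nan
        d1[f_] = vv
    d1.update({
        F.EVER_DEPRESSED_FIELD: ever_dep.astype(float),
        F.EVER_DISINTERESTED_FIELD: ever_dis.astype(float),
        F.DUR_DEPRESSED_FIELD: dur_dep.astype(float),
        F.DUR_DISINTEREST_FIELD: dur_dis.astype(float),
        F.SEEN_GP_FIELD: seen_gp.astype(float),
        F.SEEN_PSYCH_FIELD: seen_psych.astype(float),
        F.AGE_FIRST_EPISODE_FIELD: age_onset,
        "site": site, "age": age, "sex": sex, "head_size": head_size,
        "head_motion_rest": m_rest, "head_motion_task": m_task,
        "scan_date": scan_date, "latency_days": latency,
    })
    for j, c in enumerate(columns):
        d1[c] = X1[:, j]
    t1 = pd.DataFrame(d1)

    d2 = {"subject_id": sid[r], "timepoint": 2}
    for f_, v in items2.items():
        d2[f_] = v[r]
    for f_ in (list(F.PHQ9_FIELDS) + list(F.GAD7_FIELDS)
               + list(F.DEPRESSION_STATUS_FIELDS)
               + [F.AGE_FIRST_EPISODE_FIELD]):
        d2[f_] = np.nan
    d2.update({
        "site": site[r], "age": age2[r], "sex": sex[r],
        "head_size": head_size[r], "head_motion_rest": m_rest2[r],
        "head_motion_task": m_task2[r], "scan_date": date2[r],
        "latency_days": np.nan,
    })
    for j, c in enumerate(columns):
        d2[c] = X2[r, j]
    t2 = pd.DataFrame(d2)

    table = pd.concat([t1, t2[t1.columns]], ignore_index=True)

    if not return_truth:
        return table
    truth = SimTruth(
        z=z, z2=z2, z_online=z_online, rho_y=rho_y, rho_x=rho_x,
        signal_scale=alpha, idp_columns=columns, factor_of_idp=factor_of_idp,
        factor_modality=factor_modality, factor_signal=a_f, factor_loading=l,
        stable_share=lam_f, confound_betas=betas, retest_ids=retest_ids)
    return table, truth


# --------------------------------------------------------------------------
# short-interval survey retest (online-panel style validation study)
# --------------------------------------------------------------------------

def simulate_survey_retest(n: int = 134, interval_days: int = 7,
                           seed: int = 0, stable_share: float = 0.88,
                           n_attention_fail: int = 3,
                           n_fast_complete: int = 44) -> pd.DataFrame:
    """Two-timepoint questionnaire records with quality-filter columns.

    Emulates an online-panel validation study: ``n`` participants complete
    RDS-4 and PHQ-9 items twice, ``interval_days`` apart. ``stable_share``
    is the shared variance fraction of the item propensities across the two
    timepoints (1.0 reproduces identical responses). Exactly
    ``n_attention_fail`` participants fail the attention checks and a
    disjoint ``n_fast_complete`` finish faster than the 172.5 s minimum
    duration, so the standard quality filters can be exercised.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if n_attention_fail + n_fast_complete > n:
        raise ValueError("attention-fail and fast-complete counts exceed n")
    if not (0.0 <= stable_share <= 1.0):
        raise ValueError("stable_share must be in [0, 1]")
    rng = np.random.default_rng(seed)

    def propensities(rng, n, n_items, lam):
        zq = rng.standard_normal((n, 1))
        eq = rng.standard_normal((n, n_items))
        return lam * zq + np.sqrt(1.0 - lam ** 2) * eq

    frames = []
    s = stable_share
    stable = {k: propensities(rng, n, len(_ITEM_MODELS[k][0]),
                              _ITEM_MODELS[k][3])
              for k in ("rds4", "phq9")}
    perm = rng.permutation(n)
    fail_ids = np.zeros(n, dtype=bool)
    fail_ids[perm[:n_attention_fail]] = True
    fast_ids = np.zeros(n, dtype=bool)
    fast_ids[perm[n_attention_fail:n_attention_fail + n_fast_complete]] = True

    for t, day in ((1, 0), (2, interval_days)):
        d = {"subject_id": [f"M{i:04d}" for i in range(n)],
             "timepoint": t, "day": day}
        for key in ("rds4", "phq9"):
            fields_, codes, probs, lam, _ = _ITEM_MODELS[key]
            cuts = norm.ppf(np.cumsum(probs)[:-1])
            fresh = propensities(rng, n, len(fields_), lam)
            prop = np.sqrt(s) * stable[key] + np.sqrt(1.0 - s) * fresh
            mat = np.asarray(codes)[np.searchsorted(cuts, prop, side="left")]
            for j, f_ in enumerate(fields_):
                d[f_] = mat[:, j]
        dur = 180.0 + rng.exponential(120.0, n)
        dur[fast_ids] = rng.uniform(60.0, 170.0, int(fast_ids.sum()))
        d["completion_seconds"] = dur
        d["attention_pass"] = (~fail_ids).astype(int)
        frames.append(pd.DataFrame(d))
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# I/O: CSV with a sidecar column map carrying provenance
# --------------------------------------------------------------------------

def column_map(table: pd.DataFrame) -> dict:
    """Column -> {kind, field_id/modality} map for a phenotype table."""
    item_fields = set()
    for fields_, *_ in _ITEM_MODELS.values():
        item_fields.update(fields_)
    item_fields.update(F.DEPRESSION_STATUS_FIELDS)
    item_fields.add(F.AGE_FIRST_EPISODE_FIELD)
    out = {}
    for c in table.columns:
        if c in ("subject_id", "timepoint"):
            out[c] = {"kind": "key"}
        elif c in item_fields:
            out[c] = {"kind": "item", "field_id": c}
        elif c in F.CONFOUND_COLUMNS or c == "latency_days":
            out[c] = {"kind": "confound"}
        elif c.startswith("idp_"):
            out[c] = {"kind": "idp", "modality": F.modality_of(c)}
        else:
            out[c] = {"kind": "other"}
    return out


def write_phenotypes(table: pd.DataFrame, path, map_path=None,
                     config: SimConfig | None = None, sep=",") -> None:
    """Write a phenotype table plus a YAML sidecar column map.

    The sidecar echoes the generating seed and config for provenance.
    """
    table.to_csv(path, sep=sep, index=False)
    if map_path is not None:
        doc = {"columns": column_map(table)}
        if config is not None:
            doc["provenance"] = {"seed": config.seed,
                                 "config": json.loads(
                                     json.dumps(config.to_dict()))}
        with open(map_path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def read_phenotypes(path, map_path=None, sep=","):
    """Read a phenotype table (and optionally its sidecar column map)."""
    table = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    if map_path is None:
        return table
    with open(map_path) as fh:
        doc = yaml.safe_load(fh)
    return table, doc
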