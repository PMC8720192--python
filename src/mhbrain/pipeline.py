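"""End-to-end workflow binding all stages, with cached file outputs.

Each stage reads its inputs from the workspace directory written by earlier
stages and writes its own outputs there, so the pipeline is resumable and
every intermediate is inspectable. ``run_pipeline`` executes the full
sequence on a synthetic cohort:

simulate -> score -> cohort -> preprocess -> cca -> effects -> reliability
-> psychometrics

No stage mutates its inputs; numeric outputs are deterministic under a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fields as F
from . import cca as cca_mod
from .cohort import build_cohort, flow_report
from .effects import effect_size_table, modality_box_summary
from .preprocess import (GroupPCA, build_confound_design, knn_impute,
                         residualize)
from .psychometrics import (equipercentile_link, ks_two_sample,
                            latency_binned_correlation, spearman)
from .reliability import (modality_icc_summary, reliability_table,
                          subgroup_icc)
from .scoring import score_table
from .synthetic import SimConfig, read_phenotypes, simulate_cohort, \
    write_phenotypes

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    outdir: str = "mhbrain_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    phenotype_path: str | None = None     # use an existing table instead
    motion_threshold: float = 0.2         # mm, strict "greater than"
    variance_target: float = 0.5
    n_perm: int = 2000
    frac_exploratory: float = 2 / 3
    knn_k: int = 1
    latency_bin_width: float = 250.0

    def __post_init__(self):
        if not (0.0 < self.variance_target <= 1.0):
            raise ValueError("variance_target must be in (0, 1]")
        if not (0.0 < self.frac_exploratory < 1.0):
            raise ValueError("frac_exploratory must be in (0, 1)")
        if self.n_perm < 0:
            raise ValueError("n_perm must be >= 0")

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d


def _outdir(config: RunConfig) -> Path:
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _write_provenance(config: RunConfig, out: Path) -> None:
    from . import __version__
    doc = {"config": config.to_dict(), "version": __version__}
    (out / "provenance.json").write_text(json.dumps(doc, indent=2))


def stage_simulate(config: RunConfig) -> pd.DataFrame:
    out = _outdir(config)
    sim = dataclasses.replace(config.sim, seed=config.seed)
    table = simulate_cohort(sim)
    write_phenotypes(table, out / "phenotypes.csv",
                     out / "column_map.yaml", sim)
    _write_provenance(config, out)
    return table

def _load_table(config: RunConfig) -> pd.DataFrame:
    out = _outdir(config)
    path = config.phenotype_path or out / "phenotypes.csv"
    if not Path(path).exists():
        raise FileNotFoundError(
            f"stage simulate: phenotype table {path} not found")
    return read_phenotypes(path)


def stage_score(config: RunConfig) -> pd.DataFrame:
    out = _outdir(config)
    scores = score_table(_load_table(config))
    scores.to_csv(out / "scores.csv", index=False)
    return scores


def stage_cohort(config: RunConfig) -> pd.DataFrame:
    out = _outdir(config)
    table = _load_table(config)
    scores = pd.read_csv(out / "scores.csv", dtype={"subject_id": str})
    assignment = build_cohort(table, scores, seed=config.seed,
                              frac_exploratory=config.frac_exploratory,
                              motion_threshold=config.motion_threshold)
    assignment.to_csv(out / "cohort.csv", index=False)
    (out / "flow_report.txt").write_text(flow_report(assignment))
    return assignment


def _sample_rows(table, scores, assignment, group):
    ids = assignment.loc[assignment["group"] == group, "subject_id"]
    t = table[(table["timepoint"] == 1)
              & table["subject_id"].isin(set(ids))].reset_index(drop=True)
    s = scores[(scores["timepoint"] == 1)
               & scores["subject_id"].isin(set(ids))]
    s = s.set_index("subject_id").loc[t["subject_id"]].reset_index()
    return t, s


def _deconfound_sample(table, scores, knn_k):
    """Within-sample residualization of IDPs and scores, then imputation.

    Returns (residual IDP frame with missing cells, imputed IDP frame,
    residual score frame keeping the raw depression status alongside).
    """
    design = build_confound_design(table)
    idp_cols = F.idp_columns(table.columns)
    resid = residualize(table[idp_cols].to_numpy(), design)
    groups = np.array([F.GROUP_OF_MODALITY[F.modality_of(c)]
                       for c in idp_cols])
    imputed = knn_impute(resid, k=knn_k, groups=groups)
    resid_df = pd.DataFrame(resid, columns=idp_cols)
    imp_df = pd.DataFrame(imputed, columns=idp_cols)
    y = residualize(scores[list(F.SCORE_COLUMNS)].to_numpy(), design)
    y_df = pd.DataFrame(y, columns=list(F.SCORE_COLUMNS))
    y_df["depression_status_raw"] = scores["depression_status"].to_numpy()
    return resid_df, imp_df, y_df


def stage_preprocess(config: RunConfig) -> dict:
    out = _outdir(config)
    table = _load_table(config)
    scores = pd.read_csv(out / "scores.csv", dtype={"subject_id": str})
    assignment = pd.read_csv(out / "cohort.csv", dtype={"subject_id": str})

    bundles = {}
    pca = None
    for group in ("exploratory", "confirmatory"):
        t, s = _sample_rows(table, scores, assignment, group)
        resid_df, imp_df, y_df = _deconfound_sample(t, s, config.knn_k)
        if group == "exploratory":
            pca = GroupPCA(config.variance_target).fit(imp_df)
            for g, model in pca.models_.items():
                model.save(out / f"pca_{g}.json")
        comp = pca.transform(imp_df)   # exploratory loadings, never refit
        comp_df = pd.DataFrame(
            comp, columns=[f"comp_{j}" for j in range(comp.shape[1])])
        comp_df.insert(0, "subject_id", t["subject_id"])
        comp_df.to_csv(out / f"{group}_components.csv", index=False)
        y_out = y_df.copy()
        y_out.insert(0, "subject_id", t["subject_id"])
        y_out.to_csv(out / f"{group}_scores_resid.csv", index=False)
        resid_out = resid_df.copy()
        resid_out.insert(0, "subject_id", t["subject_id"])
        resid_out.to_csv(out / f"{group}_idps_resid.csv", index=False)
        bundles[group] = {"components": comp_df, "scores": y_out,
                          "idps_resid": resid_out}
    bundles["pca"] = pca
    return bundles


def stage_cca(config: RunConfig) -> dict:
    out = _outdir(config)
    Xe = pd.read_csv(out / "exploratory_components.csv")
    Ye = pd.read_csv(out / "exploratory_scores_resid.csv")
    Xc = pd.read_csv(out / "confirmatory_components.csv")
    Yc = pd.read_csv(out / "confirmatory_scores_resid.csv")
    idps_e = pd.read_csv(out / "exploratory_idps_resid.csv")

    comp_cols = [c for c in Xe.columns if c.startswith("comp_")]
    y_cols = list(F.SCORE_COLUMNS)
    model = cca_mod.PermutationCCA(n_perm=config.n_perm,
                                   random_state=config.seed)
    model.fit(Xe[comp_cols].to_numpy(), Ye[y_cols].to_numpy())

    idp_cols = [c for c in idps_e.columns if c.startswith("idp_")]
    loadings = cca_mod.uv_loadings(
        model, idps_e[idp_cols], mode=0,
        modalities=[F.modality_of(c) for c in idp_cols])
    loadings.to_csv(out / "loadings.csv", index=False)

    r_conf, p_conf = cca_mod.replicate(
        model, Xc[comp_cols].to_numpy(), Yc[y_cols].to_numpy())
    doc = {
        "r": model.r_.tolist(),
        "p_perm": model.p_perm_.tolist() if config.n_perm else None,
        "subjects_per_variable": model.subjects_per_variable_,
        "A": model.A_.tolist(), "B": model.B_.tolist(),
        "r_confirmatory": r_conf.tolist(),
        "p_confirmatory_bonferroni": p_conf.tolist(),
        "bonferroni_threshold_loadings":
            loadings.attrs["bonferroni_threshold"],
        "seed": config.seed,
        "pca_files": sorted(p.name for p in out.glob("pca_*.json")),
    }
    (out / "cca_model.json").write_text(json.dumps(doc, indent=2))
    return {"model": model, "loadings": loadings,
            "r_confirmatory": r_conf, "p_confirmatory": p_conf}


def stage_effects(config: RunConfig) -> pd.DataFrame:
    out = _outdir(config)
    loadings = pd.read_csv(out / "loadings.csv")
    idps_c = pd.read_csv(out / "confirmatory_idps_resid.csv")
    scores_c = pd.read_csv(out / "confirmatory_scores_resid.csv")
    selection = loadings.loc[loadings["significant"], "idp"]
    sc = scores_c.rename(columns={"depression_status": "_ds_resid"})
    sc = sc.rename(columns={"depression_status_raw": "depression_status"})
    table = effect_size_table(idps_c, sc, selection)
    table.to_csv(out / "effects.csv", index=False)
    (out / "effects_summary.json").write_text(
        json.dumps(modality_box_summary(table), indent=2))
    return table


def stage_reliability(config: RunConfig) -> pd.DataFrame:
    out = _outdir(config)
    table = _load_table(config)
    scores = pd.read_csv(out / "scores.csv", dtype={"subject_id": str})
    assignment = pd.read_csv(out / "cohort.csv", dtype={"subject_id": str})
    ids = set(assignment.loc[assignment["group"] == "retest", "subject_id"])

    idp_cols = F.idp_columns(table.columns)
    frames = {}
    for tp in (1, 2):
        t = table[(table["timepoint"] == tp)
                  & table["subject_id"].isin(ids)]
        t = t.sort_values("subject_id").reset_index(drop=True)
        design = build_confound_design(t)
        resid = residualize(t[idp_cols].to_numpy(), design)
        groups = np.array([F.GROUP_OF_MODALITY[F.modality_of(c)]
                           for c in idp_cols])
        frames[tp] = (t, pd.DataFrame(knn_impute(resid, config.knn_k,
                                                 groups), columns=idp_cols))
    t1, scan1 = frames[1]
    t2, scan2 = frames[2]
    if not (t1["subject_id"].to_numpy() == t2["subject_id"].to_numpy()).all():
        raise ValueError("retest timepoints not aligned")
    interval = t2["scan_date"].to_numpy() - t1["scan_date"].to_numpy()

    s = scores.set_index(["subject_id", "timepoint"])["rds4"]
    rds1 = s.loc[[(i, 1) for i in t1["subject_id"]]].to_numpy()
    rds2 = s.loc[[(i, 2) for i in t1["subject_id"]]].to_numpy()
    rds_change = rds2 - rds1

    rel = reliability_table(scan1, scan2, interval_days=interval,
                            rds_change=rds_change)
    rel.to_csv(out / "reliability.csv", index=False)
    sub = subgroup_icc(scan1, scan2, rds_change)
    sub.to_csv(out / "reliability_subgroups.csv", index=False)
    summary = {
        "icc_a1": modality_icc_summary(rel, "icc_a1"),
        "icc_interval_adj": modality_icc_summary(rel, "icc_interval_adj"),
        "icc_rds_change_adj": modality_icc_summary(rel,
                                                   "icc_rds_change_adj"),
    }
    (out / "reliability_summary.json").write_text(
        json.dumps(summary, indent=2))
    return rel


def stage_psychometrics(config: RunConfig) -> dict:
    out = _outdir(config)
    table = _load_table(config)
    scores = pd.read_csv(out / "scores.csv", dtype={"subject_id": str})
    assignment = pd.read_csv(out / "cohort.csv", dtype={"subject_id": str})
    t, s = _sample_rows(table, scores, assignment, "exploratory")

    measures = list(F.SCORE_COLUMNS)
    mat = pd.DataFrame(np.nan, index=measures, columns=measures)
    for i, a in enumerate(measures):
        for b in measures[i:]:
            rho = 1.0 if a == b else spearman(s[a], s[b])[0]
            mat.loc[a, b] = mat.loc[b, a] = rho
    mat.to_csv(out / "score_correlations.csv")

    ks = {}
    status = s["depression_status"].to_numpy()
    for m in ("rds4", "phq9", "gad7", "n12"):
        stat, p = ks_two_sample(s.loc[status == 1, m], s.loc[status == 0, m])
        ks[m] = {"statistic": stat, "p": p}
    (out / "ks_by_depression_status.json").write_text(json.dumps(ks,
                                                                 indent=2))

    links = {}
    for a, b in (("rds4", "phq9"), ("rds4", "n12"), ("n12", "gad7")):
        link = equipercentile_link(s[a], s[b])
        link.to_csv(out / f"linking_{a}_to_{b}.csv", index=False)
        links[(a, b)] = link

    lat = latency_binned_correlation(
        s["rds4"], s["phq9"], t["latency_days"],
        bin_width=config.latency_bin_width)
    lat.to_csv(out / "latency_binned_correlation.csv", index=False)
    return {"correlations": mat, "ks": ks, "links": links, "latency": lat}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the per-stage results bundle."""
    results = {}
    name = "simulate"
    try:
        results["table"] = (stage_simulate(config)
                            if config.phenotype_path is None
                            else _load_table(config))
        for name, fn in (("scores", stage_score),
                         ("cohort", stage_cohort),
                         ("preprocess", stage_preprocess),
                         ("cca", stage_cca),
                         ("effects", stage_effects),
                         ("reliability", stage_reliability),
                         ("psychometrics", stage_psychometrics)):
            results[name] = fn(config)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
    return results
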