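"""UK Biobank data-field identifiers and imaging-modality groupings.

Column names for questionnaire items follow the UKB showcase data-field IDs
so that synthetic tables and real UKB extracts share one code path. Imaging
derived phenotypes (IDPs) are tagged with a modality label; modalities are
grouped into the three blocks (resting, structural, task) that are reduced
separately before the canonical correlation analysis.
"""

from __future__ import annotations

# --- questionnaire item fields (Table-2 style inventory) -------------------

#: Recent Depressive Symptoms: depressed mood, disinterest, restlessness,
#: tiredness over the past two weeks, coded 1-4, summed range 4-16.
RDS4_FIELDS = ("2050", "2060", "2070", "2080")

#: Patient Health Questionnaire, nine items coded 0-3, range 0-27.
PHQ9_FIELDS = (
    "20514", "20510", "20517", "20519", "20511",
    "20507", "20508", "20518", "20513",
)

#: Generalized Anxiety Disorder scale, seven items coded 0-3, range 0-21.
GAD7_FIELDS = ("20506", "20509", "20520", "20515", "20516", "20505", "20512")

#: Eysenck Neuroticism, twelve yes/no items coded 0/1, range 0-12.
N12_FIELDS = (
    "1920", "1930", "1940", "1950", "1960", "1970",
    "1980", "1990", "2000", "2010", "2020", "2030",
)

#: Inputs to the probable-depression-status rule.
EVER_DEPRESSED_FIELD = "4598"
EVER_DISINTERESTED_FIELD = "4631"
DUR_DEPRESSED_FIELD = "4609"        # weeks
DUR_DISINTEREST_FIELD = "5375"      # weeks
SEEN_GP_FIELD = "2090"
SEEN_PSYCH_FIELD = "2100"
DEPRESSION_STATUS_FIELDS = (
    EVER_DEPRESSED_FIELD, EVER_DISINTERESTED_FIELD,
    DUR_DEPRESSED_FIELD, DUR_DISINTEREST_FIELD,
    SEEN_GP_FIELD, SEEN_PSYCH_FIELD,
)

#: Self-reported age at first depressive episode (late-onset screen).
AGE_FIRST_EPISODE_FIELD = "20433"

SCORE_COLUMNS = ("rds4", "phq9", "gad7", "n12", "depression_status")

# --- confounds -------------------------------------------------------------

CONFOUND_COLUMNS = (
    "site", "age", "sex", "head_size",
    "head_motion_rest", "head_motion_task", "scan_date",
)

# --- imaging modalities ----------------------------------------------------

#: Modality tags attached to IDP columns.
MODALITIES = (
    "amplitude", "full-edge", "partial-edge",     # resting-state fMRI
    "volume", "area", "thickness", "FA", "MD", "T2star", "WMH",  # structure
    "task",                                       # task fMRI
)

#: Modality blocks reduced separately by PCA before the CCA.
MODALITY_GROUPS = {
    "resting": ("amplitude", "full-edge", "partial-edge"),
    "structural": ("volume", "area", "thickness", "FA", "MD", "T2star", "WMH"),
    "task": ("task",),
}

GROUP_OF_MODALITY = {
    m: g for g, mods in MODALITY_GROUPS.items() for m in mods
}

#: Test-retest reporting categories. White-matter hyperintensity volume is
#: counted with the volume measures.
RELIABILITY_CATEGORY = {
    "area": "area",
    "volume": "volume",
    "WMH": "volume",
    "thickness": "CT",
    "FA": "FA",
    "MD": "MD",
    "T2star": "T2",
    "task": "TA",
    "amplitude": "AMP",
    "full-edge": "FNT",
    "partial-edge": "PNT",
}

#: IDP inventory sizes of the full UKB release (used for Bonferroni scopes
#: when the analysis is run at UKB scale).
UKB_IDP_COUNTS = {"resting": 3466, "structural": 346, "task": 16}


def idp_columns(columns, modality: str | None = None) -> list[str]:
    """Select IDP columns (named ``idp_<modality>_<k>``) from a column list."""
    out = []
    for c in columns:
        if not c.startswith("idp_"):
            continue
        if modality is not None and c.split("_")[1] != modality:
            continue
        out.append(c)
    return out


def modality_of(column: str) -> str:
    """Modality tag of an IDP column name."""
    if not column.startswith("idp_"):
        raise ValueError(f"not an IDP column: {column!r}")
    return column.split("_")[1]
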