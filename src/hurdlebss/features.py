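"""Claims-data feature engineering for low-back-pain (LBP) consultation prediction.

Turns long-format claims events (one row per billed diagnosis / fee-schedule
entry, indexed by billing quarter relative to the cohort examination quarter
``Q0``) plus one-row-per-subject cohort records into

* the candidate-variable design matrix used by the subset search, and
* the primary outcome: the number of LBP-specific ICD-10 codes billed during
  the follow-up year (quarters ``Q1..Q4``).

Quarter windows
---------------
``history``   Q-7..Q-4   any previous occurrence of LBP codes
``baseline``  Q-3..Q0    the year before the examination (billing quarters)
``acute``     Q0 only    codes confined to the examination quarter
``follow-up`` Q1..Q4     the outcome year; never enters any predictor

LBP codes are the dorsopathy chapter M40-M54, excluding thoracic and cervical
diagnoses (configurable exclusion list; the default excludes cervical rubrics
and site-coded entries whose site digit marks occipito-atlanto-axial,
cervical, cervicothoracic or thoracic involvement).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LBP_EXCLUSIONS",
    "CERVICOTHORACIC_SITE_DIGITS",
    "is_lbp_code",
    "lbp_mask",
    "derive_candidates",
    "build_design",
    "compute_outcome",
    "compute_outcomes",
    "compute_charlson",
    "link_records",
    "LinkageResult",
    "levenshtein",
]

_ICD_RE = re.compile(r"^[A-Z]\d{2}(?:\.\d{1,2})?$")

#: Cervical/thoracic rubrics excluded from the LBP definition by default.
#: Prefix semantics: "M50" drops the whole cervical-disc category, "M54.2"
#: drops cervicalgia including site-coded descendants.
DEFAULT_LBP_EXCLUSIONS = ("M50", "M53.0", "M53.1", "M54.2")

#: Site (5th character) digits marking occipito-atlanto-axial (1), cervical
#: (2), cervicothoracic (3) and thoracic (4) involvement in site-coded
#: M-chapter codes such as M54.02.
CERVICOTHORACIC_SITE_DIGITS = frozenset("1234")

QUARTER_MIN, QUARTER_MAX = -7, 4
HISTORY_QUARTERS = range(-7, -3)
BASELINE_QUARTERS = range(-3, 1)
FOLLOWUP_QUARTERS = range(1, 5)

_GP_GROUPS = frozenset({"general_practitioner"})
_SPECIALIST_GROUPS = frozenset({"orthopedist", "neurologist"})


class MalformedCodeError(ValueError):
    """An ICD-10 code does not match ``letter + 2 digits [+ .site digits]``."""


def _validate_code(code: str) -> str:
    code = str(code).strip().upper()
    if not _ICD_RE.match(code):
        raise MalformedCodeError(f"malformed ICD-10 code: {code!r}")
    return code


def is_lbp_code(
    icd10_code: str,
    exclusions: tuple[str, ...] = DEFAULT_LBP_EXCLUSIONS,
    exclude_site_digits: frozenset[str] = CERVICOTHORACIC_SITE_DIGITS,
) -> bool:
    """True iff *icd10_code* counts as a lumbar-spine (LBP) diagnosis.

    A code qualifies when its three-character category lies in M40..M54 and
    it is not excluded, either by prefix match against *exclusions* or by a
    cervical/thoracic site digit (the second decimal digit of site-coded
    codes, e.g. M54.02).
    """
    code = _validate_code(icd10_code)
    if code[0] != "M" or not 40 <= int(code[1:3]) <= 54:
        return False
    for excl in exclusions:
        if code.startswith(excl):
            return False
    dot = code.find(".")
    if dot >= 0 and len(code) - dot - 1 == 2 and code[-1] in exclude_site_digits:
        return False
    return True


def lbp_mask(codes: pd.Series, **kwargs) -> np.ndarray:
    """Vectorised :func:`is_lbp_code` over a Series (unique-code memoised)."""
    table = {c: is_lbp_code(c, **kwargs) for c in pd.unique(codes.astype(str))}
    return codes.astype(str).map(table).to_numpy(dtype=bool)


# ---------------------------------------------------------------------------
# Charlson comorbidity index (Quan et al. 2005 ICD-10 coding, original weights)
# ---------------------------------------------------------------------------

# (category, weight, tuple of ICD-10 prefixes). Hierarchy rules below ensure
# each condition contributes once and severe forms supersede mild ones.
_CHARLSON_MAP: tuple[tuple[str, int, tuple[str, ...]], ...] = (
    ("mi", 1, ("I21", "I22", "I25.2")),
    ("chf", 1, ("I09.9", "I11.0", "I13.0", "I13.2", "I25.5", "I42.0",
                "I42.5", "I42.6", "I42.7", "I42.8", "I42.9", "I43", "I50",
                "P29.0")),
    ("pvd", 1, ("I70", "I71", "I73.1", "I73.8", "I73.9", "I77.1", "I79.0",
                "I79.2", "K55.1", "K55.8", "K55.9", "Z95.8", "Z95.9")),
    ("cevd", 1, ("G45", "G46", "H34.0", "I60", "I61", "I62", "I63", "I64",
                 "I65", "I66", "I67", "I68", "I69")),
    ("dementia", 1, ("F00", "F01", "F02", "F03", "F05.1", "G30", "G31.1")),
    ("copd", 1, ("I27.8", "I27.9", "J40", "J41", "J42", "J43", "J44", "J45",
                 "J46", "J47", "J60", "J61", "J62", "J63", "J64", "J65",
                 "J66", "J67", "J68.4", "J70.1", "J70.3")),
    ("rheum", 1, ("M05", "M06", "M31.5", "M32", "M33", "M34", "M35.1",
                  "M35.3", "M36.0")),
    ("ulcer", 1, ("K25", "K26", "K27", "K28")),
    ("liver_mild", 1, ("B18", "K70.0", "K70.1", "K70.2", "K70.3", "K70.9",
                       "K71.3", "K71.4", "K71.5", "K71.7", "K73", "K74",
                       "K76.0", "K76.2", "K76.3", "K76.4", "K76.8", "K76.9",
                       "Z94.4")),
    ("diab_simple", 1, tuple(f"E1{i}.{d}" for i in range(5) for d in "01689")),
    ("diab_compl", 2, tuple(f"E1{i}.{d}" for i in range(5) for d in "23457")),
    ("paralysis", 2, ("G04.1", "G11.4", "G80.1", "G80.2", "G81", "G82",
                      "G83.0", "G83.1", "G83.2", "G83.3", "G83.4", "G83.9")),
    ("renal", 2, ("I12.0", "I13.1", "N03.2", "N03.3", "N03.4", "N03.5",
                  "N03.6", "N03.7", "N05.2", "N05.3", "N05.4", "N05.5",
                  "N05.6", "N05.7", "N18", "N19", "N25.0", "Z49.0", "Z49.1",
                  "Z49.2", "Z94.0", "Z99.2")),
    ("cancer", 2, tuple(f"C{i:02d}" for i in list(range(0, 27))
                        + list(range(30, 35)) + list(range(37, 42))
                        + [43] + list(range(45, 59)) + list(range(60, 77))
                        + list(range(81, 86)) + [88] + list(range(90, 98)))),
    ("liver_severe", 3, ("I85.0", "I85.9", "I86.4", "I98.2", "K70.4",
                         "K71.1", "K72.1", "K72.9", "K76.5", "K76.6",
                         "K76.7")),
    ("metastatic", 6, ("C77", "C78", "C79", "C80")),
    ("aids", 6, ("B20", "B21", "B22", "B23", "B24")),
)

# severe form supersedes the mild one when both are coded
_CHARLSON_HIERARCHY = {
    "diab_simple": "diab_compl",
    "liver_mild": "liver_severe",
    "cancer": "metastatic",
}


def compute_charlson(icd10_codes) -> int:
    """Charlson comorbidity index from a code list (Quan 2005 ICD-10 coding).

    Each condition category counts once regardless of how many of its codes
    appear; complicated diabetes, moderate/severe liver disease and
    metastatic cancer supersede their milder counterparts.
    """
    codes = [_validate_code(c) for c in icd10_codes]
    present: set[str] = set()
    for cat, _w, prefixes in _CHARLSON_MAP:
        if any(c.startswith(p) for c in codes for p in prefixes):
            present.add(cat)
    for mild, severe in _CHARLSON_HIERARCHY.items():
        if severe in present:
            present.discard(mild)
    weights = {cat: w for cat, w, _ in _CHARLSON_MAP}
    return int(sum(weights[c] for c in present))


# ---------------------------------------------------------------------------
# Candidate variables and outcome
# ---------------------------------------------------------------------------

_AGE_BREAKS = (40, 70)  # <40, 40-69, >69


def age_category(age_years: int) -> str:
    if age_years < _AGE_BREAKS[0]:
        return "<40"
    if age_years < _AGE_BREAKS[1]:
        return "40-69"
    return ">69"


def _check_quarters(quarters: np.ndarray) -> None:
    if len(quarters) and (quarters.min() < QUARTER_MIN or quarters.max() > QUARTER_MAX):
        bad = quarters[(quarters < QUARTER_MIN) | (quarters > QUARTER_MAX)]
        raise ValueError(f"claims quarters outside [{QUARTER_MIN}, {QUARTER_MAX}]: {sorted(set(bad))}")


def derive_candidates(events: pd.DataFrame, cohort_row,
                      exclusions: tuple[str, ...] = DEFAULT_LBP_EXCLUSIONS,
                      two_q_as_count: bool = True,
                      acute_as_count: bool = True) -> dict:
    """Derive the claims-side candidate variables for one subject.

    *events* holds that subject's rows (columns ``quarter``, ``icd10_code``,
    ``provider_group``, ``event_kind``); *cohort_row* is a mapping with the
    cohort covariates (at least ``age_years``).  Only history (Q-7..Q-4) and
    baseline (Q-3..Q0) windows are read -- follow-up rows are ignored, so no
    outcome information can leak into the predictors.
    """
    ev = pd.DataFrame(events)
    if len(ev):
        _check_quarters(ev["quarter"].to_numpy())
        diag = ev[ev["event_kind"] == "diagnosis"]
        is_lbp = (lbp_mask(diag["icd10_code"], exclusions=exclusions)
                  if len(diag) else np.zeros(0, bool))
        lbp_diag = diag[is_lbp]
    else:
        diag = ev
        lbp_diag = ev

    hist = lbp_diag[lbp_diag["quarter"].between(-7, -4)] if len(lbp_diag) else lbp_diag
    base = lbp_diag[lbp_diag["quarter"].between(-3, 0)] if len(lbp_diag) else lbp_diag

    n_base = len(base)
    base_quarters = set(base["quarter"]) if n_base else set()
    two_q_met = len(base_quarters) >= 2
    acute_met = n_base > 0 and base_quarters == {0}

    n_codes_2q = (n_base if two_q_met else 0) if two_q_as_count else int(two_q_met)
    acute = (n_base if acute_met else 0) if acute_as_count else int(acute_met)

    # physician specialties / imaging / interventions: baseline-window events
    # tied to back-pain care (LBP diagnoses and fee-schedule entries)
    if len(ev):
        care = ev[ev["quarter"].between(-3, 0)
                  & ((ev["event_kind"] == "fee_schedule")
                     | ev.index.isin(base.index))]
        groups = set(care["provider_group"])
    else:
        groups = set()
    saw_gp = bool(groups & _GP_GROUPS)
    saw_spec = bool(groups & _SPECIALIST_GROUPS)
    if saw_gp and saw_spec:
        visited = "gp_and_specialist"
    elif saw_gp:
        visited = "gp_only"
    elif saw_spec:
        visited = "specialist_only"
    else:
        visited = "none"

    window_diag = diag[diag["quarter"] <= 0] if len(diag) else diag
    m54_only = n_base > 0 and bool(
        base["icd10_code"].astype(str).str.upper().str.startswith("M54").all())

    return {
        "subject_id": cohort_row["subject_id"] if "subject_id" in cohort_row else None,
        "age_category": age_category(int(cohort_row["age_years"])),
        "history_lbp": len(hist) > 0,
        "n_codes_2q": n_codes_2q,
        "acute_codes": acute,
        "any_baseline_lbp": n_base > 0,
        "visited_specialties": visited,
        "imaging": "radiologist" in groups,
        "intervention": "intervention" in groups,
        "m54_only": m54_only,
        "charlson_index": compute_charlson(window_diag["icd10_code"]) if len(window_diag) else 0,
    }


def compute_outcome(events: pd.DataFrame,
                    exclusions: tuple[str, ...] = DEFAULT_LBP_EXCLUSIONS) -> int:
    """Primary outcome for one subject: LBP diagnosis codes billed in Q1..Q4."""
    ev = pd.DataFrame(events)
    if not len(ev):
        return 0
    _check_quarters(ev["quarter"].to_numpy())
    fu = ev[(ev["event_kind"] == "diagnosis") & ev["quarter"].between(1, 4)]
    if not len(fu):
        return 0
    return int(lbp_mask(fu["icd10_code"], exclusions=exclusions).sum())


def compute_outcomes(claims: pd.DataFrame, subject_ids,
                     exclusions: tuple[str, ...] = DEFAULT_LBP_EXCLUSIONS) -> pd.DataFrame:
    """Vectorised outcome table (``subject_id``, ``y``) for all subjects."""
    _check_quarters(claims["quarter"].to_numpy())
    fu = claims[(claims["event_kind"] == "diagnosis") & claims["quarter"].between(1, 4)]
    fu = fu[lbp_mask(fu["icd10_code"], exclusions=exclusions)] if len(fu) else fu
    counts = fu.groupby("subject_id").size()
    y = pd.Series(0, index=pd.Index(subject_ids, name="subject_id"), dtype=int)
    y.loc[counts.index.intersection(y.index)] = counts
    return y.rename("y").reset_index()


# ---------------------------------------------------------------------------
# Full design matrix
# ---------------------------------------------------------------------------

#: dummy coding of the cohort covariates; reference levels follow the
#: published presentation (age <40, male, single, no activity, no radiation)
COHORT_DUMMIES = {
    "age_40_69": lambda c: (c["age_years"] >= 40) & (c["age_years"] < 70),
    "age_gt_69": lambda c: c["age_years"] >= 70,
    "female": lambda c: c["sex"] == "female",
    "household_income_100eur": lambda c: c["household_income_100eur"],
    "nrs_back_pain": lambda c: c["nrs_back_pain"],
    "radiating_gluteal": lambda c: c["radiating_pain"] == "gluteal",
    "radiating_to_knee": lambda c: c["radiating_pain"] == "to_knee",
    "radiating_to_lower_leg": lambda c: c["radiating_pain"] == "to_lower_leg",
    "disc_prolapse_history": lambda c: c["disc_prolapse_history"],
    "competing_1": lambda c: c["competing_diseases"] == "1",
    "competing_gt1": lambda c: c["competing_diseases"] == ">1",
    "family_married_partner": lambda c: c["family_status"] == "married_partner",
    "family_separated": lambda c: c["family_status"] == "separated",
    "family_widowed": lambda c: c["family_status"] == "widowed",
    "activity_1_2h": lambda c: c["physical_activity"] == "1-2h",
    "activity_gt_2h": lambda c: c["physical_activity"] == ">2h",
    "benzodiazepine_use": lambda c: c["benzodiazepine_use"],
    "opioid_use": lambda c: c["opioid_use"],
}

CLAIMS_COLUMNS = [
    "history_lbp", "n_codes_2q", "acute_codes", "any_baseline_lbp",
    "m54_only", "imaging", "intervention", "charlson_index",
    "visited_gp_only", "visited_specialist_only", "visited_gp_and_specialist",
]


def build_design(claims: pd.DataFrame, cohort: pd.DataFrame,
                 exclusions: tuple[str, ...] = DEFAULT_LBP_EXCLUSIONS,
                 two_q_as_count: bool = True,
                 acute_as_count: bool = True) -> pd.DataFrame:
    """Candidate design matrix for all subjects (vectorised).

    Numeric/boolean columns: the claims-derived candidates plus dummy-coded
    cohort covariates.  Missing cohort cells propagate as NaN (the imputation
    stage owns them); claims-derived columns are always complete because an
    absent claims row simply means "no events".
    """
    cohort = cohort.set_index("subject_id", drop=False)
    idx = cohort.index
    _check_quarters(claims["quarter"].to_numpy())

    diag = claims[claims["event_kind"] == "diagnosis"].copy()
    diag_lbp = diag[lbp_mask(diag["icd10_code"], exclusions=exclusions)] if len(diag) else diag

    def per_subject(frame, func, default):
        out = pd.Series(default, index=idx)
        if len(frame):
            got = func(frame)
            out.loc[got.index.intersection(idx)] = got
        return out

    hist = diag_lbp[diag_lbp["quarter"].between(-7, -4)]
    history_lbp = per_subject(hist, lambda f: f.groupby("subject_id").size() > 0, False)

    base = diag_lbp[diag_lbp["quarter"].between(-3, 0)]
    n_base = per_subject(base, lambda f: f.groupby("subject_id").size(), 0)
    n_quarters = per_subject(base, lambda f: f.groupby("subject_id")["quarter"].nunique(), 0)
    only_q0 = per_subject(base, lambda f: f.groupby("subject_id")["quarter"].agg(
        lambda q: set(q) == {0}), False)

    two_q_met = n_quarters >= 2
    acute_met = (n_base > 0) & only_q0
    n_codes_2q = (n_base.where(two_q_met, 0) if two_q_as_count
                  else two_q_met.astype(int))
    acute = (n_base.where(acute_met, 0) if acute_as_count
             else acute_met.astype(int))

    m54 = per_subject(base, lambda f: f.groupby("subject_id")["icd10_code"].agg(
        lambda c: c.astype(str).str.upper().str.startswith("M54").all()), False)
    m54_only = (n_base > 0) & m54

    care = claims[claims["quarter"].between(-3, 0)
                  & ((claims["event_kind"] == "fee_schedule")
                     | claims.index.isin(base.index))]
    grp = care.groupby("subject_id")["provider_group"]
    saw_gp = per_subject(care, lambda f: grp.agg(lambda g: bool(set(g) & _GP_GROUPS)), False)
    saw_spec = per_subject(care, lambda f: grp.agg(lambda g: bool(set(g) & _SPECIALIST_GROUPS)), False)
    imaging = per_subject(care, lambda f: grp.agg(lambda g: "radiologist" in set(g)), False)
    interv = per_subject(care, lambda f: grp.agg(lambda g: "intervention" in set(g)), False)

    window_diag = diag[diag["quarter"] <= 0]
    charlson = per_subject(
        window_diag,
        lambda f: f.groupby("subject_id")["icd10_code"].agg(compute_charlson), 0)

    design = pd.DataFrame(index=idx)
    for name, fn in COHORT_DUMMIES.items():
        design[name] = fn(cohort)
        if design[name].dtype == bool:
            design[name] = design[name].astype(float)
        else:
            design[name] = pd.to_numeric(design[name], errors="coerce")
    # categorical cohort covariates with missing cells: dummies must stay NaN
    for cat_col, dummies in (("radiating_pain", ["radiating_gluteal", "radiating_to_knee",
                                                 "radiating_to_lower_leg"]),
                             ("competing_diseases", ["competing_1", "competing_gt1"]),
                             ("family_status", ["family_married_partner", "family_separated",
                                                "family_widowed"]),
                             ("physical_activity", ["activity_1_2h", "activity_gt_2h"])):
        na = cohort[cat_col].isna()
        if na.any():
            design.loc[na, dummies] = np.nan

    design["history_lbp"] = history_lbp.astype(float)
    design["n_codes_2q"] = n_codes_2q.astype(float)
    design["acute_codes"] = acute.astype(float)
    design["any_baseline_lbp"] = (n_base > 0).astype(float)
    design["m54_only"] = m54_only.astype(float)
    design["imaging"] = imaging.astype(float)
    design["intervention"] = interv.astype(float)
    design["charlson_index"] = charlson.astype(float)
    design["visited_gp_only"] = (saw_gp & ~saw_spec).astype(float)
    design["visited_specialist_only"] = (~saw_gp & saw_spec).astype(float)
    design["visited_gp_and_specialist"] = (saw_gp & saw_spec).astype(float)
    design["age_m54_interaction"] = design["age_40_69"] * design["m54_only"]
    return design


# ---------------------------------------------------------------------------
# Record linkage
# ---------------------------------------------------------------------------

def levenshtein(a: str, b: str) -> int:
    """Edit distance between two strings (edlib backend)."""
    import edlib
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class LinkageResult:
    """Deterministic linkage of cohort and claims identifier records.

    Candidate pairs are blocked on exact birth date; names are upper-cased
    before comparison.  Exact agreement on all fields is an
    ``exact_match``; small disagreements (total Levenshtein distance over
    surname + name, plus 1 for a sex mismatch, up to ``max_review_distance``)
    are flagged ``possible_match_review`` rather than decided.
    """
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_skipped_missing_birth_date: int = 0


def link_records(cohort_ids: pd.DataFrame, claims_ids: pd.DataFrame,
                 max_review_distance: int = 2) -> LinkageResult:
    required = {"surname", "name", "birth_date", "sex"}
    for side, frame in (("cohort", cohort_ids), ("claims", claims_ids)):
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"{side} records lack columns: {sorted(missing)}")

    def clean(frame, id_col):
        f = frame.copy()
        bad = f["birth_date"].isna()
        f = f[~bad]
        f["surname_u"] = f["surname"].astype(str).str.upper()
        f["name_u"] = f["name"].astype(str).str.upper()
        return f, int(bad.sum())

    co, skip_a = clean(cohort_ids, "cohort_id")
    cl, skip_b = clean(claims_ids, "claims_id")
    if skip_a or skip_b:
        warnings.warn(f"skipped {skip_a + skip_b} records with missing birth date")

    rows = []
    for bd, co_block in co.groupby("birth_date"):
        cl_block = cl[cl["birth_date"] == bd]
        for _, a in co_block.iterrows():
            for _, b in cl_block.iterrows():
                d = (levenshtein(a["surname_u"], b["surname_u"])
                     + levenshtein(a["name_u"], b["name_u"])
                     + (0 if a["sex"] == b["sex"] else 1))
                if d == 0:
                    status = "exact_match"
                elif d <= max_review_distance:
                    status = "possible_match_review"
                else:
                    status = "non_match"
                rows.append({"cohort_id": a["subject_id"], "claims_id": b["subject_id"],
                             "distance": d, "status": status})
    pairs = pd.DataFrame(rows, columns=["cohort_id", "claims_id", "distance", "status"])
    return LinkageResult(pairs=pairs,
                         n_skipped_missing_birth_date=skip_a + skip_b)
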