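"""Screening flowchart and classification rules.

Implements the trial-inclusion screen (launch window, therapeutic
intervention, patient population, data errors), intervention-class
assignment with standard-of-care placebo reassignment, the trial-level
class aggregation, the disease-stage window from structured cues, and the
seven-category taxonomy of drug trials based on regulatory status and
molecular target.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .config import DEFAULT_RULES, DISEASES, DRUG_CATEGORIES
from .eligibility import CriteriaCount, ScoreWindow
from .registry_io import InterventionArm, LookupTables, TrialRecord

__all__ = [
    "ScreeningDecision", "DrugCategory", "AnnotatedTrial",
    "ContradictoryCues", "map_diseases", "classify_arm", "classify_arms",
    "reassign_soc_placebo", "screen_trial", "assign_trial_class",
    "categorize_drug_trial", "assign_stage_window",
    "annotations_to_frame", "frame_to_annotations",
]


class ContradictoryCues(ValueError):
    """Stage cues that cannot describe one contiguous window."""


@dataclass(frozen=True)
class ScreeningDecision:
    included: bool
    exclusion_reason: Optional[str] = None
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class DrugCategory:
    """One of the seven mutually exclusive drug-trial categories."""
    value: str
    repurposed_subtype: Optional[str] = None   # {other_nd_disease, other_indication}

    def __post_init__(self) -> None:
        if self.value not in DRUG_CATEGORIES:
            raise ValueError(f"unknown drug category {self.value!r}")
        if (self.repurposed_subtype is not None) != (self.value == "repurposed"):
            raise ValueError("repurposed_subtype set iff value == repurposed")


def _token_pattern(tokens: Sequence[str]) -> re.Pattern:
    alts = sorted((re.escape(t) for t in tokens), key=len, reverse=True)
    return re.compile(r"(?<![a-z0-9])(?:" + "|".join(alts) + r")(?![a-z0-9])")


_PATTERN_CACHE: dict[tuple[str, ...], re.Pattern] = {}


def _tokens_match(label: str, tokens: Sequence[str]) -> bool:
    key = tuple(tokens)
    pat = _PATTERN_CACHE.get(key)
    if pat is None:
        pat = _PATTERN_CACHE[key] = _token_pattern(tokens)
    return bool(pat.search(label))


def map_diseases(conditions: Iterable[str], rules: dict | None = None
                 ) -> tuple[str, ...]:
    """Map free-text condition strings to the studied disease codes."""
    terms = (rules or DEFAULT_RULES)["disease_terms"]
    hits = set()
    for cond in conditions:
        low = cond.lower()
        for disease, tokens in terms.items():
            if _tokens_match(low, tokens):
                hits.add(disease)
    return tuple(d for d in DISEASES if d in hits)


def classify_arm(arm: InterventionArm, lookups: LookupTables | None = None,
                 rules: dict | None = None) -> InterventionArm:
    """Assign an intervention class to one arm.

    The registry's declared type is ignored (it is inconsistent even for
    identical interventions); the class follows a deterministic rule
    cascade over the normalized label: explicit placebo tokens, drug-map
    hit, behavioral intent (even if a device is involved), procedure list,
    device tokens, non-therapeutic tokens, else other. An empty label
    classifies as none.
    """
    rules = rules or DEFAULT_RULES
    label = arm.normalized_label
    canonical = None
    if not label:
        cls = "none"
    elif _tokens_match(label, rules["placebo_tokens"]):
        cls = "placebo"
    elif lookups is not None and (canonical := lookups.canonicalize(label)):
        cls = "drug"
    elif _tokens_match(label, rules["behavioral_tokens"]):
        cls = "behavioral"
    elif _tokens_match(label, rules["procedure_tokens"]):
        cls = "procedure"
    elif _tokens_match(label, rules["device_tokens"]):
        cls = "device"
    elif _tokens_match(label, rules["none_tokens"]):
        cls = "none"
    else:
        cls = "other"
    return dataclasses.replace(arm, assigned_class=cls,
                               canonical_drug_name=canonical)


def classify_arms(arms: Sequence[InterventionArm],
                  lookups: LookupTables | None = None,
                  rules: dict | None = None) -> list[InterventionArm]:
    return [classify_arm(a, lookups, rules) for a in arms]


def reassign_soc_placebo(arms: Sequence[InterventionArm],
                         lookups: LookupTables,
                         trial_year: Optional[int],
                         diseases: Sequence[str]) -> list[InterventionArm]:
    """Reclassify standard-of-care comparator arms as placebo.

    If at least one arm tests an experimental drug while another arm's drug
    was already FDA-approved for a disease of the trial in a year at or
    before the trial's launch year, the approved-drug arm counts as a
    placebo arm. Never changes the number of arms and only moves classes
    toward placebo.
    """
    if trial_year is None:
        return list(arms)

    def soc(arm: InterventionArm) -> bool:
        if arm.assigned_class != "drug" or not arm.canonical_drug_name:
            return False
        info = lookups.drug_info.get(arm.canonical_drug_name)
        if info is None or info.nd_approval is None:
            return False
        disease, year = info.nd_approval
        return disease in diseases and year <= trial_year

    drug_arms = [a for a in arms if a.assigned_class == "drug"]
    experimental = [a for a in drug_arms if not soc(a)]
    if not experimental:
        return list(arms)
    return [dataclasses.replace(a, assigned_class="placebo") if soc(a) else a
            for a in arms]


def screen_trial(record: TrialRecord, rules: dict | None = None,
                 lookups: LookupTables | None = None) -> ScreeningDecision:
    """Apply the inclusion flowchart to one record.

    Exclusion reasons are tested in flowchart order — launch window, lack
    of therapeutic intervention, population (healthy volunteers only, wrong
    disease, caregiver-targeted), then data errors — and the first failing
    test is recorded. Arms must already be classified. Records with an
    indeterminate population are included with a warning.
    """
    rules = rules or DEFAULT_RULES
    lo, hi = rules["launch_window"]
    warnings: list[str] = []

    if record.start_date is not None and record.start_date.year < lo:
        return ScreeningDecision(False, "pre_2000_launch")

    classes = {a.assigned_class for a in record.arms}
    if None in classes:
        raise ValueError(f"{record.nct_id}: arms not classified before screening")
    if not classes or classes <= {"none", "placebo"}:
        return ScreeningDecision(False, "no_therapeutic_intervention")

    diseases = map_diseases(record.conditions, rules)
    if record.healthy_volunteers and not diseases:
        return ScreeningDecision(False, "healthy_volunteers_only")
    if not diseases:
        return ScreeningDecision(False, "wrong_disease")
    low_title = record.title.lower()
    caregiver = _tokens_match(low_title, rules["caregiver_tokens"]) or any(
        _tokens_match(c.lower(), rules["caregiver_tokens"])
        for c in record.conditions)
    if caregiver:
        return ScreeningDecision(False, "caregiver_targeted")

    if record.start_date is None:
        return ScreeningDecision(False, "data_error")
    if lookups is not None:
        drug_arms = [a for a in record.arms
                     if a.assigned_class == "drug" and a.canonical_drug_name]
        if drug_arms and not any(
                lookups.label_matches_canonical(record.title,
                                                a.canonical_drug_name)
                for a in drug_arms):
            # intervention arms inconsistent with the trial's own title
            return ScreeningDecision(False, "data_error")

    if not record.conditions:
        warnings.append("indeterminate population; included by default")
    return ScreeningDecision(True, None, tuple(warnings))


def assign_trial_class(arms: Sequence[InterventionArm],
                       rules: dict | None = None
                       ) -> tuple[Optional[str], bool]:
    """Aggregate arm classes to one trial-level class.

    Priority order drug > device > procedure > behavioral > other over
    non-placebo, non-none arms; also reports whether any arm is a
    placebo/standard-of-care control. A trial whose arms are all
    placebo/none has no class (None) — the screening invariant should have
    excluded it.
    """
    priority = (rules or DEFAULT_RULES)["class_priority"]
    classes = {a.assigned_class for a in arms} - {"placebo", "none", None}
    controlled = any(a.assigned_class == "placebo" for a in arms)
    for cls in priority:
        if cls in classes:
            return cls, controlled
    return None, controlled


def categorize_drug_trial(drug_canonicals: Sequence[str],
                          diseases: Sequence[str],
                          start_year: Optional[int],
                          lookups: LookupTables,
                          ) -> tuple[Optional[DrugCategory], Optional[str]]:
    """Assign one of the 7 drug-trial categories.

    Decision cascade over the trial's tested (experimental) drugs:

    1-2. a tested drug is FDA-approved for a disease of the trial — before
         the approval year -> ``nd_approved_pre_approval``, at/after ->
         ``nd_approved_post_approval``;
    3.   a tested drug holds full approval for a different studied disease
         (subtype ``other_nd_disease``) or any other indication
         (``other_indication``) -> ``repurposed``;
    4.   an unapproved single entity whose target already has an approved
         drug for some disease -> ``new_drug_established_target``;
    5.   a combination whose components are all approved drugs or
         supplements -> ``approved_combination``;
    6-7. otherwise a novel hypothesis, split by whether any (target gene,
         trial disease) pair carries human genetic support.

    Returns (category, None) or (None, reason) when no tested drug name
    resolves. Every drug trial therefore receives exactly one category or
    an explicit missing reason.
    """
    infos = [lookups.drug_info[c] for c in drug_canonicals
             if c in lookups.drug_info]
    if not infos:
        return None, "unresolved drug name"
    if start_year is None:
        return None, "unknown launch year"

    for info in infos:
        if info.nd_approval and info.nd_approval[0] in diseases:
            if start_year < info.nd_approval[1]:
                return DrugCategory("nd_approved_pre_approval"), None
            return DrugCategory("nd_approved_post_approval"), None
    for info in infos:
        if info.nd_approval:  # approved for a different studied disease
            return DrugCategory("repurposed", "other_nd_disease"), None
    for info in infos:
        if info.other_approval:
            return DrugCategory("repurposed", "other_indication"), None
    for info in infos:
        if not info.components and info.target_genes & lookups.approved_target_genes:
            return DrugCategory("new_drug_established_target"), None
    for info in infos:
        if info.components:
            comps = [lookups.drug_info.get(c) for c in info.components]
            if all(c is not None and (c.other_approval or c.supplement_flag)
                   for c in comps):
                return DrugCategory("approved_combination"), None
    assoc = lookups.associations
    if len(assoc):
        pairs = set(zip(assoc["gene"], assoc["disease"]))
        for info in infos:
            for gene in info.target_genes:
                for disease in diseases:
                    if (gene, disease) in pairs:
                        return DrugCategory("novel_genetic_support"), None
    return DrugCategory("novel_no_genetic_support"), None


# Structured stage cues -> stage each cue makes eligible. "Required" cues
# pin the whole population (diagnosis_required) or set a floor
# (biomarker_positive_required); the window spans the eligible stages.
_CUE_STAGE = {
    "at_risk_age_only": 0,
    "presymptomatic_carriers": 0,
    "biomarker_positive_required": 1,
    "detectable_impairment_allowed": 2,
    "mci_allowed": 3,
    "diagnosis_allowed": 4,
    "diagnosis_required": 4,
}


def assign_stage_window(cues: Iterable[str]) -> tuple[int, int]:
    """Map structured stage cues to the eligible (stage_min, stage_max).

    The cross-disease staging runs 0 (at-risk) through 4 (diagnosed).
    Raises :class:`ContradictoryCues` for combinations that cannot describe
    one population (e.g. diagnosis required alongside pre-symptomatic
    eligibility, or no cues at all).
    """
    cues = set(cues)
    unknown = cues - set(_CUE_STAGE)
    if unknown:
        raise ContradictoryCues(f"unknown stage cues: {sorted(unknown)}")
    if not cues:
        raise ContradictoryCues("no stage cues supplied")
    stages = {_CUE_STAGE[c] for c in cues}
    if "diagnosis_required" in cues and min(stages) < 4:
        raise ContradictoryCues("diagnosis required but earlier stages cued")
    if "at_risk_age_only" in cues and max(stages) > 0:
        raise ContradictoryCues("at-risk-only population but later stages cued")
    return min(stages), max(stages)


@dataclass
class AnnotatedTrial:
    """A trial record plus every derived label.

    Excluded trials carry exactly one exclusion reason and no downstream
    annotations; ``drug_category`` is set only for included drug trials.
    """
    record: TrialRecord
    included: bool
    exclusion_reason: Optional[str] = None
    diseases: tuple[str, ...] = ()
    stage_min: Optional[int] = None
    stage_max: Optional[int] = None
    criteria: Optional[CriteriaCount] = None
    score_window: Optional[ScoreWindow] = None
    severity_scale: str = "none"          # {MMSE, HY, other, none}
    trial_class: Optional[str] = None
    placebo_soc_controlled: bool = False
    drug_canonicals: tuple[str, ...] = ()
    drug_category: Optional[DrugCategory] = None
    category_missing_reason: Optional[str] = None
    duration_years: Optional[float] = None
    patient_years: Optional[float] = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.included and self.exclusion_reason is not None:
            raise ValueError(f"{self.record.nct_id}: included with a reason")
        if not self.included and self.exclusion_reason is None:
            raise ValueError(f"{self.record.nct_id}: excluded without reason")
        if (self.stage_min is not None and self.stage_max is not None
                and self.stage_min > self.stage_max):
            raise ValueError(f"{self.record.nct_id}: stage_min > stage_max")


_OPT = lambda v: "" if v is None else v


def annotations_to_frame(trials: Sequence[AnnotatedTrial]) -> pd.DataFrame:
    """Flatten annotations into the canonical TSV-ready table."""
    rows = []
    for t in trials:
        r = t.record
        win = t.score_window
        crit = t.criteria
        rows.append({
            "nct_id": r.nct_id,
            "included": int(t.included),
            "exclusion_reason": _OPT(t.exclusion_reason),
            "year": r.start_date.year if r.start_date else "",
            "start_date": r.start_date.isoformat() if r.start_date else "",
            "completion_date": (r.completion_date.isoformat()
                                if r.completion_date else ""),
            "enrollment_count": _OPT(r.enrollment_count),
            "enrollment_type": r.enrollment_type,
            "phase": r.phase,
            "sector": r.sponsor_sector,
            "overall_status": r.overall_status,
            "diseases": ";".join(t.diseases),
            "stage_min": _OPT(t.stage_min),
            "stage_max": _OPT(t.stage_max),
            "n_inclusion": _OPT(crit.n_inclusion) if crit else "",
            "n_exclusion": _OPT(crit.n_exclusion) if crit else "",
            "criteria_total": _OPT(crit.total) if crit else "",
            "criteria_method": crit.method if crit else "",
            "severity_scale": t.severity_scale,
            "win_min": _OPT(win.min_score) if win else "",
            "win_max": _OPT(win.max_score) if win else "",
            "win_min_inferred": int(win.min_inferred) if win else "",
            "win_max_inferred": int(win.max_inferred) if win else "",
            "trial_class": _OPT(t.trial_class),
            "placebo_soc_controlled": int(t.placebo_soc_controlled),
            "drug_canonicals": ";".join(t.drug_canonicals),
            "drug_category": t.drug_category.value if t.drug_category else "",
            "repurposed_subtype": (t.drug_category.repurposed_subtype or ""
                                   if t.drug_category else ""),
            "category_missing_reason": _OPT(t.category_missing_reason),
            "duration_years": _OPT(t.duration_years),
            "patient_years": _OPT(t.patient_years),
            "warnings": ";".join(t.warnings),
        })
    columns = list(rows[0].keys()) if rows else _ANNOTATION_COLUMNS
    return pd.DataFrame(rows, columns=columns)


_ANNOTATION_COLUMNS = [
    "nct_id", "included", "exclusion_reason", "year", "start_date",
    "completion_date", "enrollment_count", "enrollment_type", "phase",
    "sector", "overall_status", "diseases", "stage_min", "stage_max",
    "n_inclusion", "n_exclusion", "criteria_total", "criteria_method",
    "severity_scale", "win_min", "win_max", "win_min_inferred",
    "win_max_inferred", "trial_class", "placebo_soc_controlled",
    "drug_canonicals", "drug_category", "repurposed_subtype",
    "category_missing_reason", "duration_years", "patient_years", "warnings",
]


def typed_annotation_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Convert a string-typed annotation frame (as read from TSV) to the
    numeric dtypes the statistics module expects. Empty cells become NaN,
    never zero."""
    out = frame.copy()
    numeric = ["included", "year", "enrollment_count", "stage_min",
               "stage_max", "n_inclusion", "n_exclusion", "criteria_total",
               "win_min", "win_max", "win_min_inferred", "win_max_inferred",
               "placebo_soc_controlled", "duration_years", "patient_years"]
    for col in numeric:
        if col in out.columns:
            out[col] = pd.to_numeric(out[col].replace("", pd.NA),
                                     errors="raise")
    return out


def frame_to_annotations(frame: pd.DataFrame,
                         records: Sequence[TrialRecord]
                         ) -> list[AnnotatedTrial]:
    """Rehydrate AnnotatedTrial objects (round-trip inverse of
    :func:`annotations_to_frame`); records are matched by NCT id."""
    by_id = {r.nct_id: r for r in records}
    out = []
    for row in frame.itertuples(index=False):
        crit = None
        if row.criteria_method:
            crit = CriteriaCount(
                None if row.n_inclusion == "" else int(row.n_inclusion),
                None if row.n_exclusion == "" else int(row.n_exclusion),
                method=row.criteria_method)
        win = None
        if row.win_min != "":
            win = ScoreWindow(row.severity_scale, float(row.win_min),
                              float(row.win_max),
                              bool(int(row.win_min_inferred)),
                              bool(int(row.win_max_inferred)))
        category = None
        if row.drug_category:
            category = DrugCategory(row.drug_category,
                                    row.repurposed_subtype or None)
        out.append(AnnotatedTrial(
            record=by_id[row.nct_id],
            included=bool(int(row.included)),
            exclusion_reason=row.exclusion_reason or None,
            diseases=tuple(d for d in row.diseases.split(";") if d),
            stage_min=None if row.stage_min == "" else int(row.stage_min),
            stage_max=None if row.stage_max == "" else int(row.stage_max),
            criteria=crit,
            score_window=win,
            severity_scale=row.severity_scale,
            trial_class=row.trial_class or None,
            placebo_soc_controlled=bool(int(row.placebo_soc_controlled)),
            drug_canonicals=tuple(
                d for d in row.drug_canonicals.split(";") if d),
            drug_category=category,
            category_missing_reason=row.category_missing_reason or None,
            duration_years=(None if row.duration_years == ""
                            else float(row.duration_years)),
            patient_years=(None if row.patient_years == ""
                           else float(row.patient_years)),
            warnings=tuple(w for w in row.warnings.split(";") if w),
        ))
    return out
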