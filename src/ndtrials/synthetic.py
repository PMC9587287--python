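"""Synthetic trial-registry generator with known ground truth.

Generates registry collections whose statistical structure matches the
landscape the analysis pipeline assumes — yearly launch counts, sector /
intervention-class / phase mixtures, disease-stage distributions with an
ordinal temporal drift, criteria counts with linear yearly slopes, MMSE and
Hoehn & Yahr eligibility windows with drifting bounds, heavy-tailed
enrollment, and drug arms drawn from a synthetic name pool with synonyms
and typos — so that every pipeline stage is testable without any download,
and injected trends can be scored against the generating truth.

Default parameter values are chosen to emulate the observed two-decade
neurodegenerative-disease trial landscape (2000 through a three-month slice
of 2020; ~38% industry sponsorship; ~58% drug trials; inclusion/exclusion
criteria rising from ~9 at 0.4/year in industry drug trials; MMSE bounds
drifting from 25.6/13.6 toward 27.6/17.7; H&Y bounds from 1.6/3.8 toward
1.2/3.1; ~2.7% of trials open to pre-symptomatic participants). The drug
pool, gene symbols and association table are synthetic stand-ins that
reproduce the *shape* of the curated landscape (approved, repurposed,
established-target, combination and novel entities; genetically supported
and unsupported targets), not its real names.

The per-trial latent labels are serialized as a truth sidecar that never
leaks into the record files the pipeline consumes; structured stage cues
(the input the stage-assignment rules operate on) are emitted as a separate
annotation sidecar, standing in for manual curation.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DISEASES, rules_hash, DEFAULT_RULES
from .registry_io import (DrugInfo, InterventionArm, LookupTables,
                          TrialRecord, write_registry_dir, write_records_tsv,
                          write_lookup_tables, write_manifest)

__all__ = ["GeneratorConfig", "CorruptionRates", "GenerationResult",
           "default_lookup_tables", "generate_registry", "corrupt_records",
           "write_generated"]


# ---------------------------------------------------------------------------
# Synthetic drug pool and association table

def _synonyms(name: str, idx: int) -> list[str]:
    """Deterministic synonym set: the name, a development code name and a
    plausible typo (one dropped character)."""
    code = f"{name[:2]}-{101 + idx}"
    typo = name[:4] + name[5:] if len(name) > 6 else name + "e"
    syns = [name, code]
    if typo != name:
        syns.append(typo)
    return syns


# (name, disease, approval_year, target) — FDA full approvals in the four
# studied diseases.
_ND_APPROVED = [
    ("neprazil", "AD", 1996, "CHEX1"),
    ("cognexin", "AD", 2003, "CHEX1"),
    ("memantol", "AD", 2003, "NMDR2"),
    ("dopaxel", "PD", 1975, "DOPR1"),
    ("rasagast", "PD", 2006, "MAOX1"),
    ("riluzane", "FTD_ALS", 1995, "GLUX1"),
    ("tetrabenz", "HD", 2008, "VMAT9"),
]
# (name, indication_area, approval_year, target) — full approvals elsewhere.
_REPURPOSED = [
    ("botulinax", "neurology", 1989, "SNAPX1"),
    ("metforvin", "metabolic", 1994, "AMPK3"),
    ("lisinox", "cardiovascular", 1992, "ACEX1"),
    ("pravastol", "cardiovascular", 1991, "HMGX1"),
    ("valprozine", "neurology", 1983, "HDACX1"),
    ("naltrexol", "neurology", 1984, "OPRX1"),
]
# Approved drugs never tested in this landscape (approved-only targets).
_APPROVED_UNTESTED = [
    ("statinex", "cardiovascular", 1997, "LDLX1"),
    ("omeprazine", "gastroenterology", 1990, "ATPX4"),
]
# Unapproved entities aimed at targets that already have approved drugs.
_ESTABLISHED = [("zelcognib", "AMPK3"), ("dopranex", "DOPR1")]
# Novel entities with genetically supported targets, per disease.
_NOVEL_GENETIC = {
    "AD": [("abeximab", "ABQ1", 0.68), ("tauzumab", "TAUX", 0.12),
           ("gsecanib", "GSEC1", 0.12), ("nelrimab", "NLR9", 0.08)],
    "PD": [("synucleab", "SYNQ2", 0.6), ("lurkinib", "LRK9", 0.4)],
    "FTD_ALS": [("sodumab", "SODX4", 0.4), ("granulix", "GRNX2", 0.3),
                ("corfanex", "CORF9", 0.3)],
    "HD": [("huntexan", "HTTX1", 1.0)],
}
# Novel entities without genetic support: (name, target or None, weight).
_NOVEL_NO_SUPPORT = [
    ("mapranib", "MAPX1", 0.06), ("bacetinib", "BACX1", 0.05),
    ("neuroxanib", "KINX5", 0.03), ("mitophil", "MITX2", 0.02),
    ("cerebrol", None, 0.20), ("neurovital", None, 0.18),
    ("brainex", None, 0.17), ("synaptol", None, 0.17),
    ("omegavite", None, 0.06), ("ginkgonol", None, 0.06),
]
_SUPPLEMENTS = {"omegavite", "ginkgonol"}
_COMBINATIONS = [
    ("neprazil + memantol", ("neprazil", "memantol")),
    ("omegavite + ginkgonol", ("omegavite", "ginkgonol")),
]
# Synthetic gene-disease associations: (gene, disease, first-report year,
# source). ACEX1 (a target of an approved cardiovascular drug) carries a
# back-dated candidate-gene association; GBAX1/PRKX3 are never drugged.
_ASSOCIATIONS = [
    ("ABQ1", "AD", 1991, "mendelian"),
    ("GSEC1", "AD", 1995, "mendelian"),
    ("TAUX", "AD", 1998, "mendelian"),
    ("ACEX1", "AD", 1999, "gwas"),
    ("NLR9", "AD", 2013, "gwas"),
    ("HTTX1", "HD", 1993, "mendelian"),
    ("SODX4", "FTD_ALS", 1993, "mendelian"),
    ("SYNQ2", "PD", 1997, "mendelian"),
    ("PRKX3", "PD", 1998, "mendelian"),
    ("LRK9", "PD", 2004, "mendelian"),
    ("GRNX2", "FTD_ALS", 2006, "mendelian"),
    ("GBAX1", "PD", 2009, "gwas"),
    ("CORF9", "FTD_ALS", 2011, "mendelian"),
]


def default_lookup_tables() -> LookupTables:
    """Build the synthetic drug map, approvals, targets and associations."""
    drug_map: dict[str, str] = {}
    infos: dict[str, DrugInfo] = {}
    idx = 0

    def add(name: str, *, target: Optional[str] = None,
            nd: Optional[tuple[str, int]] = None,
            other_area: Optional[str] = None,
            components: tuple[str, ...] = (),
            synonyms: Optional[list[str]] = None) -> None:
        nonlocal idx
        for syn in synonyms or _synonyms(name, idx):
            drug_map[syn] = name
        infos[name] = DrugInfo(
            canonical_name=name,
            target_genes=frozenset([target] if target else []),
            nd_approval=nd,
            other_approval=nd is not None or other_area is not None,
            other_indication_area=other_area,
            supplement_flag=name in _SUPPLEMENTS,
            target_evidence_source="drugbank" if target else None,
            components=components,
        )
        idx += 1

    for name, disease, year, target in _ND_APPROVED:
        add(name, target=target, nd=(disease, year))
    for name, area, year, target in _REPURPOSED + _APPROVED_UNTESTED:
        add(name, target=target, other_area=area)
    for name, target in _ESTABLISHED:
        add(name, target=target)
    for pool in _NOVEL_GENETIC.values():
        for name, target, _ in pool:
            add(name, target=target)
    for name, target, _ in _NOVEL_NO_SUPPORT:
        add(name, target=target)
    for name, comps in _COMBINATIONS:
        a, b = comps
        add(name, components=comps,
            synonyms=[name, f"{a}/{b}", f"{a} and {b} combination"])

    associations = pd.DataFrame(
        _ASSOCIATIONS, columns=["gene", "disease", "year", "source"])
    associations["l2g_note"] = ""
    return LookupTables(drug_map, infos, associations)


# ---------------------------------------------------------------------------
# Generator configuration

_DRUG_KINDS = ("nd_approved", "repurposed_other", "repurposed_nd",
               "established_target", "combination", "novel_genetic",
               "novel_no_support")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic registry; defaults are the study conditions."""
    seed: int = 0
    start_year: int = 2000
    end_year: int = 2020
    final_year_fraction: float = 0.25      # three months of the final year
    trials_per_year: int | Sequence[int] = 160
    # Cohort mixture: 'normal' records pass screening; the others exercise
    # each exclusion arm of the screening flowchart.
    cohort_mix: Mapping[str, float] = field(default_factory=lambda: {
        "normal": 0.91, "pre_2000": 0.02, "no_therapeutic": 0.03,
        "healthy_only": 0.02, "wrong_disease": 0.01, "caregiver": 0.01})
    sector_mix: Mapping[str, float] = field(default_factory=lambda: {
        "industry": 0.38, "other": 0.62})
    class_mix: Mapping[str, float] = field(default_factory=lambda: {
        "drug": 0.58, "behavioral": 0.16, "procedure": 0.08,
        "device": 0.08, "other": 0.10})
    # Pre-symptomatic trials are depleted for drug/device and enriched for
    # behavioral interventions.
    presymptomatic_class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "drug": 0.30, "behavioral": 0.42, "procedure": 0.06,
            "device": 0.04, "other": 0.18})
    disease_mix: Mapping[str, float] = field(default_factory=lambda: {
        "AD": 0.40, "PD": 0.35, "FTD_ALS": 0.17, "HD": 0.08})
    multi_disease_rate: float = 0.03       # second disease, non-drug trials
    phase_mix: Mapping[str, float] = field(default_factory=lambda: {
        "1": 0.20, "2": 0.35, "3": 0.25, "4": 0.10, "1/2": 0.07,
        "2/3": 0.03})
    phase_specified_industry_drug: float = 0.97
    phase_specified_other: float = 0.22
    # Ordinal stage model: P(stage <= k | t) = logistic(logit(base cdf) +
    # drift * t); positive drift shifts trials toward earlier stages.
    stage_mix_base: Sequence[float] = (0.006, 0.006, 0.015, 0.078, 0.895)
    stage_drift: float = 0.022
    stage_window_collapse_rate: float = 0.12   # stage_max = stage_min, not 4
    # Criteria counts: Poisson around intercept + slope * years-since-start;
    # the slope applies to industry drug trials, the flat slope to the rest.
    criteria_intercept: float = 9.0
    criteria_slope: float = 0.4
    criteria_slope_other: float = 0.0
    nested_bullet_rate: float = 0.08
    # Severity-scale usage (MMSE for the cognitive diseases, H&Y for PD)
    # and window parameters: bound mean at t=0, per-year drift, noise SD.
    mmse_usage_cognitive: float = 0.43
    hy_usage_pd: float = 0.66
    other_scale_usage: float = 0.06
    mmse_window_params: Mapping[str, float] = field(default_factory=lambda: {
        "min0": 13.6, "min_slope": 0.205, "min_sd": 3.0,
        "max0": 25.6, "max_slope": 0.10, "max_sd": 1.5})
    hy_window_params: Mapping[str, float] = field(default_factory=lambda: {
        "min0": 1.6, "min_slope": -0.02, "min_sd": 0.5,
        "max0": 3.8, "max_slope": -0.035, "max_sd": 0.6})
    one_sided_rate: float = 0.15
    # Enrollment: log-normal components chosen so that industry drug trials
    # are larger and less skewed (~15% enrolling <= 20, ~60% of all
    # patient-years) while other trials keep a small-trial mass (~34%
    # <= 20) plus a heavy tail whose few largest trials dominate their
    # group's patient-years.
    enrollment_dist: Mapping[str, float] = field(default_factory=lambda: {
        "mu": 3.4, "sigma": 1.0,
        "industry_drug_mu": 4.8, "industry_drug_sigma": 1.65,
        "heavy_weight": 0.012, "heavy_mu": 7.5, "heavy_sigma": 0.8,
        "preventive_shift": 0.2})
    duration_dist: Mapping[str, float] = field(default_factory=lambda: {
        "mu": 0.6, "sigma": 0.7, "preventive_shift": 0.5})
    anticipated_fraction: float = 0.30
    completion_missing_rate: float = 0.12
    month_precision_rate: float = 0.30
    completed_rate_industry_drug: float = 0.80
    completed_rate_other: float = 0.36
    placebo_rate_industry_drug: float = 0.65
    placebo_rate_other: float = 0.21
    soc_fraction: float = 0.30             # controlled drug trials using SOC
    healthy_controls_rate: float = 0.10    # disease trials also taking healthy
    drug_kind_mix: Mapping[str, float] = field(default_factory=lambda: {
        "nd_approved": 0.30, "repurposed_other": 0.30, "repurposed_nd": 0.03,
        "established_target": 0.04, "combination": 0.02,
        "novel_genetic": 0.079, "novel_no_support": 0.231})
    supported_share_drift: float = 0.0     # per-year shift into novel_genetic

    def __post_init__(self) -> None:
        for name in ("cohort_mix", "sector_mix", "class_mix",
                     "presymptomatic_class_mix", "disease_mix", "phase_mix",
                     "drug_kind_mix"):
            vec = getattr(self, name)
            if abs(sum(vec.values()) - 1.0) > 1e-6 or min(vec.values()) < 0:
                raise ValueError(f"{name} must be a probability vector")
        if abs(sum(self.stage_mix_base) - 1.0) > 1e-6:
            raise ValueError("stage_mix_base must sum to 1")
        horizon = self.end_year - self.start_year
        if (self.criteria_intercept <= 0
                or self.criteria_intercept
                + min(0.0, self.criteria_slope) * horizon <= 0):
            raise ValueError("infeasible criteria count within window")
        for params in (self.mmse_window_params, self.hy_window_params,
                       self.enrollment_dist, self.duration_dist):
            for key, value in params.items():
                if key.endswith(("_sd", "sigma")) and value <= 0:
                    raise ValueError(f"dispersion {key} must be positive")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass(frozen=True)
class CorruptionRates:
    missing_start_date: float = 0.0
    prose_only: float = 0.0
    arm_mismatch: float = 0.0


@dataclass
class GenerationResult:
    """Records, the truth sidecar, the stage-cue sidecar and the lookups."""
    records: list[TrialRecord]
    truth: pd.DataFrame
    cues: dict[str, tuple[str, ...]]
    lookups: LookupTables
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# Text rendering vocabulary

_CONDITION_NAMES = {
    "AD": ["Alzheimer Disease", "Alzheimer's Disease"],
    "PD": ["Parkinson Disease", "Parkinson's Disease"],
    "FTD_ALS": ["Amyotrophic Lateral Sclerosis", "Frontotemporal Dementia"],
    "HD": ["Huntington Disease"],
}
_WRONG_CONDITIONS = ["Multiple Sclerosis", "Ischemic Stroke", "Epilepsy"]

_INCLUSION_POOL = [
    "Aged 50 to 85 years at screening",
    "Stable medication regimen for at least 30 days",
    "Able to provide written informed consent",
    "Reliable study partner available to accompany visits",
    "Adequate visual and auditory acuity for testing",
    "Fluent in the local language",
    "Community dwelling at enrollment",
    "Willing to undergo repeated assessments",
    "Body mass index within protocol limits",
    "Able to swallow study medication",
]
_EXCLUSION_POOL = [
    "History of stroke or other significant neurological disease",
    "Current participation in another interventional study",
    "Unstable cardiac disease within the past 6 months",
    "Major psychiatric disorder requiring hospitalization",
    "Known hypersensitivity to the study intervention",
    "Pregnancy or breastfeeding",
    "Significant renal or hepatic impairment",
    "Contraindication to magnetic resonance imaging",
    "Alcohol or substance abuse within the past year",
    "Use of prohibited concomitant medications",
]
_SCALE_RENDER = {
    "MMSE": ["MMSE", "Mini-Mental State Examination (MMSE)",
             "mini-mental state examination"],
    "HY": ["Hoehn and Yahr stage", "Hoehn & Yahr stage", "H&Y stage"],
}
_OTHER_SCALES = ["UPDRS part III", "CDR", "ALSFRS-R",
                 "UHDRS total motor score", "ADAS-Cog"]
_BEHAVIORAL_POOL = [
    "aerobic exercise program", "resistance training program",
    "mediterranean diet counseling", "cognitive training program",
    "medication adherence coaching",
    "exercise program delivered via tablet device", "group dance classes",
]
_DEVICE_POOL = [
    "deep brain stimulation", "transcranial magnetic stimulation",
    "transcranial direct current stimulation",
    "vagus nerve stimulator implant",
]
_PROCEDURE_POOL = [
    "autologous stem cell transplantation", "acupuncture",
    "focused ultrasound lesioning", "fetal tissue transplantation",
]
_OTHER_POOL = [
    "music listening sessions", "art therapy sessions", "aromatherapy",
    "light exposure sessions",
]
_NONE_POOL = [
    "blood draw and biomarker sampling", "lumbar puncture for csf collection",
    "structural mri scan", "longitudinal observation only",
]
_PLACEBO_POOL = ["placebo", "matching placebo", "sugar pill", "normal saline"]
_NONDRUG_CONTROL_POOL = ["placebo", "sham stimulation", "no treatment"]
_DOSE_SUFFIXES = ["", " 50 mg", " 100 mg", " oral tablets",
                  " extended release"]
_DECLARED_TYPES = ["Drug", "Device", "Procedure", "Behavioral", "Other"]
_CLASS_POOLS = {"behavioral": _BEHAVIORAL_POOL, "device": _DEVICE_POOL,
                "procedure": _PROCEDURE_POOL, "other": _OTHER_POOL}

_CUE_FOR_MIN = {0: "presymptomatic_carriers", 1: "biomarker_positive_required",
                2: "detectable_impairment_allowed", 3: "mci_allowed"}
_CUE_FOR_POINT = {0: "at_risk_age_only", 1: "biomarker_positive_required",
                  2: "detectable_impairment_allowed", 3: "mci_allowed",
                  4: "diagnosis_required"}


def _cues_for_window(smin: int, smax: int) -> tuple[str, ...]:
    if smin == smax:
        return (_CUE_FOR_POINT[smin],)
    cues = [_CUE_FOR_MIN[smin]]
    if smax == 4:
        cues.append("diagnosis_allowed")
    else:  # windows not reaching diagnosis: cue every eligible stage
        cues.extend(_CUE_FOR_MIN.get(s, "mci_allowed")
                    for s in range(smin + 1, smax + 1))
    return tuple(dict.fromkeys(cues))


def _fmt(x: float) -> str:
    return f"{x:g}"


# ---------------------------------------------------------------------------
# Generation

def _choice(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    keys = list(mix)
    return keys[rng.choice(len(keys), p=np.asarray(list(mix.values())))]


def stage_probabilities(config: "GeneratorConfig", t: float) -> np.ndarray:
    """Stage probabilities at t years into the window under the ordinal
    drift model P(stage <= k | t) = logistic(logit(base cdf_k) + drift*t)."""
    return _stage_probs(config.stage_mix_base, config.stage_drift, t)


def _stage_probs(base: Sequence[float], drift: float, t: float) -> np.ndarray:
    base = np.asarray(base, dtype=float)
    cdf = np.cumsum(base)[:-1]
    logit = np.log(cdf / (1 - cdf)) + drift * t
    shifted = 1 / (1 + np.exp(-logit))
    probs = np.diff(np.concatenate([[0.0], shifted, [1.0]]))
    return probs / probs.sum()


def _sample_mmse_window(cfg: GeneratorConfig, rng: np.random.Generator,
                        t: float) -> tuple[float, float]:
    p = cfg.mmse_window_params
    for _ in range(20):
        lo = round(float(rng.normal(p["min0"] + p["min_slope"] * t,
                                    p["min_sd"])))
        hi = round(float(rng.normal(p["max0"] + p["max_slope"] * t,
                                    p["max_sd"])))
        lo, hi = max(0, min(lo, 30)), max(0, min(hi, 30))
        if lo < hi:
            return float(lo), float(hi)
    return 10.0, 26.0


def _sample_hy_window(cfg: GeneratorConfig, rng: np.random.Generator,
                      t: float) -> tuple[float, float]:
    p = cfg.hy_window_params
    for _ in range(20):
        lo = round(2 * float(rng.normal(p["min0"] + p["min_slope"] * t,
                                        p["min_sd"]))) / 2
        hi = round(2 * float(rng.normal(p["max0"] + p["max_slope"] * t,
                                        p["max_sd"]))) / 2
        lo, hi = max(0.0, min(lo, 5.0)), max(0.0, min(hi, 5.0))
        if lo < hi:
            return lo, hi
    return 1.0, 3.0


def _render_score_phrase(scale: str, lo: float, hi: float, one_sided: str,
                         rng: np.random.Generator) -> str:
    name = _SCALE_RENDER[scale][rng.integers(len(_SCALE_RENDER[scale]))]
    step = 1.0 if scale == "MMSE" else 0.5
    if one_sided == "min":
        tmpl = rng.integers(3)
        return [f"{name} score of {_fmt(lo)} or above",
                f"{name} score >= {_fmt(lo)}",
                f"{name} score of at least {_fmt(lo)}"][tmpl]
    if one_sided == "max":
        tmpl = rng.integers(3)
        return [f"{name} score of {_fmt(hi)} or below",
                f"{name} score <= {_fmt(hi)}",
                f"{name} score of no more than {_fmt(hi)}"][tmpl]
    options = [
        f"{name} score between {_fmt(lo)} and {_fmt(hi)}",
        f"{name} score of {_fmt(lo)} to {_fmt(hi)}",
        f"{name} score {_fmt(lo)}-{_fmt(hi)}",
        f"{name} score ≥ {_fmt(lo)} and ≤ {_fmt(hi)}",
        f"{name} score of at least {_fmt(lo)} and no more than {_fmt(hi)}",
    ]
    if lo - step >= 0 and hi + step <= (30 if scale == "MMSE" else 5):
        options.append(f"{name} score > {_fmt(lo - step)} "
                       f"and < {_fmt(hi + step)}")
    return options[rng.integers(len(options))]


def _render_eligibility(rng: np.random.Generator, cfg: GeneratorConfig,
                        n_inc: int, n_exc: int, condition: str,
                        score_phrase: Optional[str]) -> str:
    style = rng.integers(5)          # -, *, bullet, "n.", "n)"

    def marker(i: int) -> str:
        return ["- ", "* ", "• ", f"{i}. ", f"{i}) "][style]

    inc_items = [f"Diagnosis of {condition} established by a specialist"]
    if score_phrase is not None:
        inc_items.append(score_phrase)
    while len(inc_items) < n_inc:
        inc_items.append(
            _INCLUSION_POOL[rng.integers(len(_INCLUSION_POOL))])
    inc_items = inc_items[:n_inc]
    exc_items = [_EXCLUSION_POOL[rng.integers(len(_EXCLUSION_POOL))]
                 for _ in range(n_exc)]

    lines = ["Inclusion Criteria:", ""]
    for i, item in enumerate(inc_items, start=1):
        lines.append(marker(i) + item)
        if rng.random() < cfg.nested_bullet_rate:
            lines.append("    - documented in the medical record")
            lines.append("    - confirmed at the screening visit")
    lines += ["", "Exclusion Criteria:", ""]
    for i, item in enumerate(exc_items, start=1):
        lines.append(marker(i) + item)
    return "\n".join(lines)


def _pick_drug(cfg: GeneratorConfig, rng: np.random.Generator,
               disease: str, year: int, t: float,
               lookups: LookupTables) -> tuple[str, str]:
    """Choose (canonical drug, kind) for a drug trial."""
    mix = dict(cfg.drug_kind_mix)
    shift = cfg.supported_share_drift * t
    mix["novel_genetic"] = max(0.0, mix["novel_genetic"] + shift)
    mix["novel_no_support"] = max(0.0, mix["novel_no_support"] - shift)
    total = sum(mix.values())
    mix = {k: v / total for k, v in mix.items()}
    kind = _choice(rng, mix)

    if kind == "nd_approved":
        pool = [n for n, d, _, _ in _ND_APPROVED if d == disease]
        return pool[rng.integers(len(pool))], kind
    if kind == "repurposed_other":
        pool = [n for n, _, _, _ in _REPURPOSED]
        return pool[rng.integers(len(pool))], kind
    if kind == "repurposed_nd":
        pool = [n for n, d, y, _ in _ND_APPROVED if d != disease]
        return pool[rng.integers(len(pool))], kind
    if kind == "established_target":
        pool = [n for n, _ in _ESTABLISHED]
        return pool[rng.integers(len(pool))], kind
    if kind == "combination":
        pool = [n for n, _ in _COMBINATIONS]
        return pool[rng.integers(len(pool))], kind
    if kind == "novel_genetic":
        pool = _NOVEL_GENETIC[disease]
        weights = np.array([w for _, _, w in pool])
        i = rng.choice(len(pool), p=weights / weights.sum())
        return pool[i][0], kind
    pool_ns = _NOVEL_NO_SUPPORT
    weights = np.array([w for _, _, w in pool_ns])
    i = rng.choice(len(pool_ns), p=weights / weights.sum())
    return pool_ns[i][0], kind


def _kind_to_category(kind: str, canonical: str, disease: str,
                      year: int) -> tuple[str, str]:
    """Latent category implied by the sampled drug kind (generator intent,
    computed independently of the curation cascade)."""
    if kind == "nd_approved":
        approval = next(y for n, d, y, _ in _ND_APPROVED if n == canonical)
        return (("nd_approved_pre_approval", "") if year < approval
                else ("nd_approved_post_approval", ""))
    if kind == "repurposed_other":
        return "repurposed", "other_indication"
    if kind == "repurposed_nd":
        return "repurposed", "other_nd_disease"
    if kind == "established_target":
        return "new_drug_established_target", ""
    if kind == "combination":
        return "approved_combination", ""
    if kind == "novel_genetic":
        return "novel_genetic_support", ""
    return "novel_no_genetic_support", ""


def _soc_drug(disease: str, year: int) -> Optional[str]:
    """An approved standard-of-care drug for the disease at the time."""
    pool = [n for n, d, y, _ in _ND_APPROVED if d == disease and y <= year]
    return pool[0] if pool else None


def generate_registry(config: GeneratorConfig,
                      lookups: Optional[LookupTables] = None
                      ) -> GenerationResult:
    """Generate a registry collection with its ground-truth sidecar.

    Byte-reproducible under a fixed seed. Eligibility text is rendered from
    the latent labels through a small template grammar (bullet styles
    sampled per trial, score windows as comparator phrases); stage cues go
    to a structured sidecar standing in for manual stage curation.
    """
    rng = np.random.default_rng(config.seed)
    lookups = lookups or default_lookup_tables()
    years = list(range(config.start_year, config.end_year + 1))
    if isinstance(config.trials_per_year, (int, np.integer)):
        per_year = {y: int(config.trials_per_year) for y in years}
    else:
        per_year = {y: int(n) for y, n in zip(years, config.trials_per_year)}
    per_year[config.end_year] = int(
        round(per_year[config.end_year] * config.final_year_fraction))

    records: list[TrialRecord] = []
    cues: dict[str, tuple[str, ...]] = {}
    rows: list[dict] = []
    serial = 0

    for year in years:
        for _ in range(per_year[year]):
            serial += 1
            nct_id = f"NCT{serial:08d}"
            cohort = _choice(rng, config.cohort_mix)
            launch_year = year
            if cohort == "pre_2000":
                launch_year = config.start_year - int(rng.integers(1, 4))
            t = launch_year - config.start_year

            sector = _choice(rng, config.sector_mix)
            disease = _choice(rng, config.disease_mix)
            diseases = [disease]

            # stage window from the ordinal drift model
            stage_probs = _stage_probs(config.stage_mix_base,
                                       config.stage_drift, max(t, 0))
            smin = int(rng.choice(5, p=stage_probs))
            if smin == 4:
                smax = 4
            else:
                smax = (smin if rng.random()
                        < config.stage_window_collapse_rate else 4)
            presymptomatic = smin <= 2

            cls_mix = (config.presymptomatic_class_mix if presymptomatic
                       else config.class_mix)
            trial_class = _choice(rng, cls_mix)
            if cohort == "no_therapeutic":
                trial_class = "none"
            elif cohort in ("healthy_only", "caregiver"):
                trial_class = "behavioral"
            if (trial_class != "drug" and cohort == "normal"
                    and rng.random() < config.multi_disease_rate):
                others = [d for d in DISEASES if d != disease]
                second = others[rng.integers(len(others))]
                diseases = sorted({disease, second},
                                  key=list(DISEASES).index)

            industry_drug = sector == "industry" and trial_class == "drug"

            # phase
            if rng.random() < (config.phase_specified_industry_drug
                               if industry_drug
                               else config.phase_specified_other):
                phase = _choice(rng, config.phase_mix)
            else:
                phase = "other_unspecified"

            # criteria counts
            slope = (config.criteria_slope if industry_drug
                     else config.criteria_slope_other)
            mu = config.criteria_intercept + slope * max(t, 0)
            total = max(2, int(rng.poisson(mu)))
            n_inc = max(1, min(total - 1, int(rng.binomial(total, 0.55))))
            n_exc = total - n_inc

            # severity-score window
            scale, lo, hi = "none", np.nan, np.nan
            min_inferred = max_inferred = False
            score_phrase = None
            u = rng.random()
            if disease == "PD":
                if u < config.hy_usage_pd:
                    scale = "HY"
                elif u < config.hy_usage_pd + config.other_scale_usage:
                    scale = "other"
            else:
                if u < config.mmse_usage_cognitive:
                    scale = "MMSE"
                elif u < config.mmse_usage_cognitive + config.other_scale_usage:
                    scale = "other"
            if scale == "MMSE":
                lo, hi = _sample_mmse_window(config, rng, max(t, 0))
            elif scale == "HY":
                lo, hi = _sample_hy_window(config, rng, max(t, 0))
            if scale in ("MMSE", "HY"):
                one_sided = ""
                if rng.random() < config.one_sided_rate:
                    one_sided = "min" if rng.random() < 0.7 else "max"
                score_phrase = _render_score_phrase(scale, lo, hi,
                                                    one_sided, rng)
                scale_top = 30.0 if scale == "MMSE" else 5.0
                if one_sided == "min":
                    hi, max_inferred = scale_top, True
                elif one_sided == "max":
                    lo, min_inferred = 0.0, True
            elif scale == "other":
                other = _OTHER_SCALES[rng.integers(len(_OTHER_SCALES))]
                a = int(rng.integers(5, 20))
                score_phrase = (f"{other} score between {a} "
                                f"and {a + int(rng.integers(5, 20))}")
            if score_phrase is not None and n_inc < 2:
                n_inc = 2  # room for the diagnosis item plus the score item

            # dates, enrollment, duration, status
            if year == config.end_year and cohort != "pre_2000":
                max_day = max(2, int(365 * config.final_year_fraction))
                day_of_year = int(rng.integers(1, max_day))
            else:
                day_of_year = int(rng.integers(1, 366))
            start = (dt.date(launch_year, 1, 1)
                     + dt.timedelta(days=day_of_year - 1))
            month_precision = bool(rng.random()
                                   < config.month_precision_rate)
            if month_precision:
                start = start.replace(day=1)

            ddist = config.duration_dist
            dur_mu = ddist["mu"] + (ddist["preventive_shift"]
                                    if presymptomatic else 0.0)
            duration = float(rng.lognormal(dur_mu, ddist["sigma"]))
            completion: Optional[dt.date] = None
            if rng.random() >= config.completion_missing_rate:
                completion = start + dt.timedelta(
                    days=int(round(duration * 365.25)))

            edist = config.enrollment_dist
            preventive_shift = (edist["preventive_shift"] if presymptomatic
                                else 0.0)
            if industry_drug:
                enr_mu = edist["industry_drug_mu"] + preventive_shift
                enr_sigma = edist["industry_drug_sigma"]
            elif rng.random() < edist["heavy_weight"]:
                enr_mu, enr_sigma = edist["heavy_mu"], edist["heavy_sigma"]
            else:
                enr_mu = edist["mu"] + preventive_shift
                enr_sigma = edist["sigma"]
            enrollment = max(1, int(round(rng.lognormal(enr_mu, enr_sigma))))
            enrollment_type = ("anticipated"
                               if rng.random() < config.anticipated_fraction
                               else "actual")
            completed_rate = (config.completed_rate_industry_drug
                              if industry_drug
                              else config.completed_rate_other)
            if rng.random() < completed_rate:
                status = "Completed"
            else:
                status = ["Recruiting", "Terminated",
                          "Active, not recruiting",
                          "Unknown status"][rng.integers(4)]

            # arms and title
            arms: list[InterventionArm] = []
            drug_canonical = ""
            drug_kind = ""
            category = subtype = ""
            controlled = False
            soc_control = False

            def declared() -> str:
                return _DECLARED_TYPES[rng.integers(len(_DECLARED_TYPES))]

            condition_pool = _CONDITION_NAMES[disease]
            condition = condition_pool[rng.integers(len(condition_pool))]
            conditions = [condition] + [
                _CONDITION_NAMES[d][0] for d in diseases if d != disease]
            healthy_flag = bool(rng.random() < config.healthy_controls_rate)

            if cohort == "no_therapeutic":
                n_arms = 1 + int(rng.random() < 0.4)
                for _ in range(n_arms):
                    label = _NONE_POOL[rng.integers(len(_NONE_POOL))]
                    arms.append(InterventionArm(label, declared()))
                title = f"Biomarker Study of {condition}"
            elif cohort == "healthy_only":
                label = _BEHAVIORAL_POOL[rng.integers(len(_BEHAVIORAL_POOL))]
                arms.append(InterventionArm(label, declared()))
                title = f"A Study of {label.title()} in Healthy Volunteers"
                conditions = ["Healthy Volunteers"]
                healthy_flag = True
            elif cohort == "wrong_disease":
                label = _BEHAVIORAL_POOL[rng.integers(len(_BEHAVIORAL_POOL))]
                wrong = _WRONG_CONDITIONS[rng.integers(len(_WRONG_CONDITIONS))]
                arms.append(InterventionArm(label, declared()))
                title = f"A Study of {label.title()} in {wrong}"
                conditions = [wrong]
                healthy_flag = False
            elif cohort == "caregiver":
                label = "support and education program"
                arms.append(InterventionArm(label, declared()))
                title = (f"Support Program for Caregivers of Patients "
                         f"With {condition}")
            elif trial_class == "drug":
                drug_canonical, drug_kind = _pick_drug(
                    config, rng, disease, launch_year, max(t, 0), lookups)
                synonyms = [s for s, c in lookups.drug_map.items()
                            if c == drug_canonical]
                synonym = synonyms[rng.integers(len(synonyms))]
                suffix = _DOSE_SUFFIXES[rng.integers(len(_DOSE_SUFFIXES))]
                arms.append(InterventionArm(synonym + suffix, declared()))
                if rng.random() < 0.15:  # second dose arm, same entity
                    suffix2 = _DOSE_SUFFIXES[rng.integers(len(_DOSE_SUFFIXES))]
                    arms.append(InterventionArm(synonym + suffix2,
                                                declared()))
                placebo_rate = (config.placebo_rate_industry_drug
                                if industry_drug
                                else config.placebo_rate_other)
                if rng.random() < placebo_rate:
                    controlled = True
                    soc = _soc_drug(disease, launch_year)
                    usable_soc = (soc is not None and soc != drug_canonical
                                  and drug_kind not in ("nd_approved",))
                    if usable_soc and rng.random() < config.soc_fraction:
                        soc_control = True
                        arms.append(InterventionArm(soc, declared()))
                    else:
                        label = _PLACEBO_POOL[rng.integers(len(_PLACEBO_POOL))]
                        arms.append(InterventionArm(label, declared()))
                category, subtype = _kind_to_category(
                    drug_kind, drug_canonical, disease, launch_year)
                title = f"A Study of {synonym.title()} in {condition}"
            else:
                pool = _CLASS_POOLS[trial_class]
                label = pool[rng.integers(len(pool))]
                arms.append(InterventionArm(label, declared()))
                placebo_rate = config.placebo_rate_other
                if rng.random() < placebo_rate:
                    controlled = True
                    ctrl = _NONDRUG_CONTROL_POOL[
                        rng.integers(len(_NONDRUG_CONTROL_POOL))]
                    arms.append(InterventionArm(ctrl, declared()))
                title = f"A Study of {label.title()} in {condition}"

            eligibility = _render_eligibility(
                rng, config, n_inc, n_exc, condition, score_phrase)
            if cohort == "healthy_only":
                eligibility = ("Inclusion Criteria:\n\n"
                               "- Healthy adult volunteers aged 18 to 65\n"
                               "- Able to provide written informed consent\n"
                               "\nExclusion Criteria:\n\n"
                               "- Any chronic neurological diagnosis\n")

            included = cohort == "normal"
            reason = {"normal": "", "pre_2000": "pre_2000_launch",
                      "no_therapeutic": "no_therapeutic_intervention",
                      "healthy_only": "healthy_volunteers_only",
                      "wrong_disease": "wrong_disease",
                      "caregiver": "caregiver_targeted"}[cohort]

            records.append(TrialRecord(
                nct_id=nct_id, title=title, start_date=start,
                start_date_month_precision=month_precision,
                completion_date=completion,
                enrollment_count=enrollment,
                enrollment_type=enrollment_type, phase=phase,
                sponsor_sector=sector, overall_status=status,
                conditions=conditions, eligibility_text=eligibility,
                healthy_volunteers=healthy_flag, arms=arms))
            cues[nct_id] = _cues_for_window(smin, smax)
            rows.append({
                "nct_id": nct_id, "cohort": cohort, "year": launch_year,
                "t": max(t, 0), "sector": sector,
                "trial_class": trial_class,
                "diseases": ";".join(diseases), "phase": phase,
                "stage_min": smin, "stage_max": smax,
                "n_inclusion": n_inc, "n_exclusion": n_exc,
                "scale": scale, "win_min": lo, "win_max": hi,
                "win_min_inferred": int(min_inferred),
                "win_max_inferred": int(max_inferred),
                "enrollment": enrollment,
                "enrollment_type": enrollment_type,
                "duration_years": (np.nan if completion is None
                                   else (completion - start).days / 365.25),
                "status": status, "controlled": int(controlled),
                "soc_control": int(soc_control),
                "drug_canonical": drug_canonical, "drug_kind": drug_kind,
                "drug_category": category, "repurposed_subtype": subtype,
                "included": int(included), "exclusion_reason": reason,
                "corrupt_missing_start": 0, "corrupt_prose": 0,
                "corrupt_arm_mismatch": 0,
            })

    truth = pd.DataFrame(rows)
    return GenerationResult(records, truth, cues, lookups, config)


def corrupt_records(result: GenerationResult,
                    rates: CorruptionRates,
                    seed: Optional[int] = None) -> GenerationResult:
    """Inject labeled data errors at the stated rates.

    Three corruption channels: missing start dates, prose-only criteria
    blocks (no recognized list), and intervention arms that no longer match
    the trial's title. The truth sidecar records each hit and the exclusion
    reason the screening flowchart is expected to produce. Rates of zero
    return an (deep-copied) identity.
    """
    rng = np.random.default_rng(result.config.seed + 7919
                                if seed is None else seed)
    records = []
    truth = result.truth.copy()
    for i, original in enumerate(result.records):
        record = dataclasses.replace(
            original, conditions=list(original.conditions),
            arms=list(original.arms))
        row = truth.iloc[i]
        reason = row["exclusion_reason"]

        if rng.random() < rates.missing_start_date:
            record.start_date = None
            record.start_date_month_precision = False
            truth.iloc[i, truth.columns.get_loc("corrupt_missing_start")] = 1
            if reason in ("", "pre_2000_launch"):
                reason = "data_error"

        if rng.random() < rates.prose_only:
            record.eligibility_text = _prose_criteria(record.eligibility_text)
            truth.iloc[i, truth.columns.get_loc("corrupt_prose")] = 1

        if rng.random() < rates.arm_mismatch:
            wrong = _wrong_drug_synonym(result.lookups, record, rng)
            if wrong is not None:
                record.arms = [
                    arm if _is_placebo_label(arm.raw_label)
                    else InterventionArm(wrong, arm.declared_type)
                    for arm in record.arms]
                truth.iloc[
                    i, truth.columns.get_loc("corrupt_arm_mismatch")] = 1
                if reason in ("", "no_therapeutic_intervention"):
                    reason = "data_error"

        truth.iloc[i, truth.columns.get_loc("exclusion_reason")] = reason
        truth.iloc[i, truth.columns.get_loc("included")] = int(reason == "")
        records.append(record)
    return GenerationResult(records, truth, dict(result.cues),
                            result.lookups, result.config)


def _is_placebo_label(label: str) -> bool:
    low = label.lower()
    return any(tok in low for tok in DEFAULT_RULES["placebo_tokens"])


def _prose_criteria(text: str) -> str:
    """Re-render a criteria block as prose (no bullet or number markers)."""
    items: dict[str, list[str]] = {"inclusion": [], "exclusion": []}
    side = "inclusion"
    score_line = None
    for line in text.splitlines():
        low = line.strip().lower()
        if low.startswith("inclusion criteria"):
            side = "inclusion"
            continue
        if low.startswith("exclusion criteria"):
            side = "exclusion"
            continue
        stripped = line.strip().lstrip("-*• ").lstrip("0123456789.) ")
        if stripped:
            if ("score" in stripped.lower()
                    or "stage" in stripped.lower()) and score_line is None:
                score_line = stripped
            else:
                items[side].append(stripped)
    parts = ["Inclusion Criteria:", "",
             "Eligible participants must satisfy all of the following: "
             + "; ".join(items["inclusion"]) + "."]
    if score_line:
        parts += ["", score_line + "."]
    parts += ["", "Exclusion Criteria:", "",
              "Participants are excluded for any of: "
              + "; ".join(items["exclusion"]) + "."]
    return "\n".join(parts)


def _wrong_drug_synonym(lookups: LookupTables, record: TrialRecord,
                        rng: np.random.Generator) -> Optional[str]:
    """A drug synonym that does not appear in the record's title."""
    title = record.title.lower()
    candidates = [syn for syn, canon in lookups.drug_map.items()
                  if not lookups.label_matches_canonical(title, canon)]
    if not candidates:
        return None
    return candidates[rng.integers(len(candidates))]


def write_generated(result: GenerationResult, outdir: str | Path,
                    write_xml: bool = True) -> dict[str, Path]:
    """Serialize a generated registry: XML directory, TSV mirror, truth and
    stage-cue sidecars, lookup tables and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if write_xml:
        paths["xml_dir"] = outdir / "xml"
        write_registry_dir(result.records, paths["xml_dir"])
    paths["records_tsv"] = outdir / "records.tsv"
    write_records_tsv(result.records, paths["records_tsv"])
    paths["truth"] = outdir / "truth.tsv"
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["cues"] = outdir / "stage_cues.tsv"
    pd.DataFrame(
        [{"nct_id": k, "cues": ";".join(v)} for k, v in result.cues.items()]
    ).to_csv(paths["cues"], sep="\t", index=False)
    lookup_paths = write_lookup_tables(result.lookups, outdir / "lookups")
    paths.update({f"lookup_{k}": v for k, v in lookup_paths.items()})
    paths["manifest"] = outdir / "generation_manifest.json"
    write_manifest({"seed": result.config.seed,
                    "config_hash": result.config.hash(),
                    "n_records": len(result.records)},
                   paths["manifest"])
    return paths


def read_stage_cues(path: str | Path) -> dict[str, tuple[str, ...]]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {row.nct_id: tuple(c for c in row.cues.split(";") if c)
            for row in frame.itertuples(index=False)}
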