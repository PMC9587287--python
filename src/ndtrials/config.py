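"""Rule tables and configuration loading.

All text-matching vocabularies used by the curation engine — intervention
class token lists, disease search terms, severity-scale synonyms, bullet
markers — live here as plain data so that they can be overridden from a
YAML file and hashed into the run manifest for provenance.
"""
from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

#: Canonical disease codes, in reporting order.
DISEASES = ("AD", "PD", "FTD_ALS", "HD")

#: Phase vocabulary. Combined phases stay distinct in storage; analyses that
#: stratify by phase map them to the lower phase (see stats.collapse_phase).
PHASES = ("1", "2", "3", "4", "1/2", "2/3", "other_unspecified")

INTERVENTION_CLASSES = ("drug", "device", "procedure", "behavioral",
                        "placebo", "other", "none")

EXCLUSION_REASONS = ("pre_2000_launch", "no_therapeutic_intervention",
                     "healthy_volunteers_only", "wrong_disease",
                     "caregiver_targeted", "data_error")

DRUG_CATEGORIES = (
    "nd_approved_pre_approval",
    "nd_approved_post_approval",
    "repurposed",
    "new_drug_established_target",
    "approved_combination",
    "novel_no_genetic_support",
    "novel_genetic_support",
)

DEFAULT_RULES: dict = {
    # Free-text condition matching -> disease codes.
    "disease_terms": {
        "AD": ["alzheimer"],
        "PD": ["parkinson"],
        "FTD_ALS": ["amyotrophic", "frontotemporal", "ftd", "ftld", "als",
                    "lou gehrig", "motor neuron disease"],
        "HD": ["huntington"],
    },
    # Intervention-class assignment cascade vocabularies. Order of
    # application: placebo -> drug map -> behavioral -> procedure -> device
    # -> none -> other.  Behavioral intent wins over device mention.
    "placebo_tokens": ["placebo", "sham", "sugar pill", "standard of care",
                       "usual care", "normal saline", "no treatment",
                       "no intervention", "waitlist", "wait list"],
    "behavioral_tokens": ["exercise", "diet", "dietary", "compliance",
                          "adherence", "training", "education", "counseling",
                          "coaching", "behavioral", "meditation", "walking",
                          "dance", "yoga", "tai chi", "cognitive stimulation"],
    "procedure_tokens": ["surgery", "surgical", "acupuncture", "transplant",
                         "transplantation", "radiation", "radiotherapy",
                         "care protocol", "lesioning"],
    "device_tokens": ["stimulation", "stimulator", "device", "implant",
                      "tdcs", "tms", "ultrasound", "electrode", "helmet",
                      "wearable"],
    "none_tokens": ["blood draw", "lumbar puncture", "biopsy", "imaging",
                    "mri", "pet scan", "observation", "questionnaire",
                    "survey", "registry", "tracer"],
    "caregiver_tokens": ["caregiver", "caregivers", "care partner", "carer",
                         "carers"],
    # Trial-level aggregation priority over non-placebo, non-none arms.
    "class_priority": ["drug", "device", "procedure", "behavioral", "other"],
    # Severity-scale mention synonyms (extensible; registry diction varies).
    "scale_synonyms": {
        "MMSE": ["mmse", "mini-mental state examination",
                 "mini mental state examination", "mini-mental"],
        "HY": ["hoehn and yahr", "hoehn & yahr", "hoehn-yahr", "h&y", "h & y"],
    },
    # Severity scales recognised as "uses a scale" but never parsed into
    # windows (the pipeline prioritises MMSE and Hoehn & Yahr).
    "other_scale_tokens": ["updrs", "cdr", "alsfrs", "uhdrs", "adas-cog",
                           "moca"],
    # Screening launch window (calendar years, inclusive).
    "launch_window": [2000, 2020],
}

#: Smallest representable increment of each severity scale; strict
#: inequalities are tightened by one step.
SCALE_STEP = {"MMSE": 1.0, "HY": 0.5}
SCALE_MAX = {"MMSE": 30.0, "HY": 5.0}


def load_rules(path: str | Path | None = None) -> dict:
    """Return the rule tables, optionally overridden from a YAML file.

    Overrides replace whole keys (lists are not merged element-wise) so a
    config file can both extend a synonym table and retire a token list.
    """
    rules = copy.deepcopy(DEFAULT_RULES)
    if path is not None:
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        if not isinstance(overrides, dict):
            raise ValueError(f"rules file {path} must contain a mapping")
        for key, value in overrides.items():
            if key not in rules:
                raise ValueError(f"unknown rule table {key!r}")
            rules[key] = value
    return rules


def rules_hash(rules: dict) -> str:
    """Stable hash of a rule-table set, recorded in the run manifest."""
    canon = json.dumps(rules, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()
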