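"""Gene-disease associations and genetic-support audits.

A drug's therapeutic hypothesis is "genetically supported" when some target
gene of the drug has a reported human genetic association (Mendelian or
GWAS) with the trial's disease. This module keeps the association table,
answers support queries, computes discovery-to-first-trial lags, tallies
the three-set target intersection (approved-drug targets, tested targets,
genetically supported targets) and tracks category shares over time.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DISEASES, DRUG_CATEGORIES
from .registry_io import LookupTables
from .stats import TrendFit, linear_trend

__all__ = [
    "GeneDiseaseAssociation", "TargetSets", "is_supported", "lag_years",
    "euler_region_counts", "support_share_by_year", "category_share_trend",
    "support_audit", "target_sets_from_annotations",
]


@dataclass(frozen=True)
class GeneDiseaseAssociation:
    gene: str
    disease: str
    year: int                      # first reported association
    source: str = "gwas"           # {mendelian, gwas}
    l2g_note: str = ""


def _pairs(associations: pd.DataFrame) -> set[tuple[str, str]]:
    return set(zip(associations["gene"], associations["disease"]))


def is_supported(target_genes: Iterable[str], disease: str,
                 associations: pd.DataFrame) -> bool:
    """True iff any target gene has an association row for the disease.

    Monotone: adding association rows can only turn False into True.
    """
    pairs = _pairs(associations)
    return any((gene, disease) in pairs for gene in target_genes)


def lag_years(association_year: Optional[int],
              first_trial_year: Optional[int]) -> Optional[int]:
    """Years from genetic discovery to first trial of the pair.

    Negative lags are permitted — a trial can pre-date the association,
    coincidentally. Missing years give a missing lag.
    """
    if association_year is None or first_trial_year is None:
        return None
    return first_trial_year - association_year


@dataclass(frozen=True)
class TargetSets:
    """The three gene sets of the target-landscape intersection."""
    approved_targets: frozenset[str]
    tested_targets: frozenset[str]
    genetic_targets: frozenset[str]


_REGIONS = ("approved_only", "tested_only", "genetic_only",
            "approved_tested", "approved_genetic", "tested_genetic",
            "all_three")


def euler_region_counts(sets: TargetSets) -> dict[str, int]:
    """Exclusive region counts of the three-set intersection.

    The seven counts partition the union, so they satisfy every
    inclusion-exclusion identity exactly.
    """
    a, t, g = (sets.approved_targets, sets.tested_targets,
               sets.genetic_targets)
    counts = dict.fromkeys(_REGIONS, 0)
    for gene in a | t | g:
        key = (gene in a, gene in t, gene in g)
        region = {
            (True, False, False): "approved_only",
            (False, True, False): "tested_only",
            (False, False, True): "genetic_only",
            (True, True, False): "approved_tested",
            (True, False, True): "approved_genetic",
            (False, True, True): "tested_genetic",
            (True, True, True): "all_three",
        }[key]
        counts[region] += 1
    return counts


def target_sets_from_annotations(frame: pd.DataFrame,
                                 lookups: LookupTables) -> TargetSets:
    """Build the three target sets from an annotated-trial table.

    Tested targets are targets of drugs appearing in included drug trials;
    genetic targets are genes with an association to any studied disease.
    """
    tested: set[str] = set()
    drug_trials = frame[(frame["included"] == 1)
                        & (frame["trial_class"] == "drug")]
    for cell in drug_trials["drug_canonicals"]:
        for canon in str(cell).split(";"):
            info = lookups.drug_info.get(canon)
            if info is not None:
                tested |= info.target_genes
    genetic = set(lookups.associations["gene"]) if len(
        lookups.associations) else set()
    return TargetSets(frozenset(lookups.approved_target_genes),
                      frozenset(tested), frozenset(genetic))


def support_audit(frame: pd.DataFrame, lookups: LookupTables) -> pd.DataFrame:
    """Audit every genetically supported (gene, disease) pair.

    For each association-table pair, counts the included drug trials whose
    tested drug targets the gene in that disease, sums their patient-years,
    and computes the discovery-to-first-trial lag. Pairs never tested get
    n_trials 0 and missing lag.
    """
    drug_trials = frame[(frame["included"] == 1)
                        & (frame["trial_class"] == "drug")]
    rows = []
    for assoc in lookups.associations.itertuples(index=False):
        gene, disease, year = assoc.gene, assoc.disease, int(assoc.year)
        n_trials = 0
        patient_years = 0.0
        any_py = False
        first_year: Optional[int] = None
        for row in drug_trials.itertuples(index=False):
            if disease not in str(row.diseases).split(";"):
                continue
            genes: set[str] = set()
            for canon in str(row.drug_canonicals).split(";"):
                info = lookups.drug_info.get(canon)
                if info is not None:
                    genes |= info.target_genes
            if gene not in genes:
                continue
            n_trials += 1
            if not pd.isna(row.patient_years):
                patient_years += float(row.patient_years)
                any_py = True
            trial_year = int(row.year)
            if first_year is None or trial_year < first_year:
                first_year = trial_year
        rows.append({
            "gene": gene, "disease": disease, "association_year": year,
            "source": assoc.source, "n_trials": n_trials,
            "patient_years": patient_years if any_py else np.nan,
            "first_trial_year": first_year if first_year is not None else np.nan,
            "lag_years": (lag_years(year, first_year)
                          if first_year is not None else np.nan),
        })
    return pd.DataFrame(rows, columns=[
        "gene", "disease", "association_year", "source", "n_trials",
        "patient_years", "first_trial_year", "lag_years"])


def mean_lag(audit: pd.DataFrame, per: str = "pair",
             positive_only: bool = True) -> Optional[float]:
    """Mean discovery-to-first-trial lag over tested pairs or targets.

    ``per='target'`` first reduces to one lag per gene (the earliest trial
    across its supported indications). ``positive_only`` restricts to pairs
    whose first trial followed the discovery, the convention for a
    "how long did translation take" summary; coincidental earlier trials
    otherwise enter with negative lags.
    """
    tested = audit[audit["n_trials"] > 0].dropna(subset=["lag_years"])
    if per == "target":
        tested = tested.sort_values(["gene", "lag_years"]).groupby(
            "gene", as_index=False).first()
    if positive_only:
        tested = tested[tested["lag_years"] >= 0]
    if not len(tested):
        return None
    return float(tested["lag_years"].mean())


def support_share_by_year(frame: pd.DataFrame) -> pd.DataFrame:
    """Per launch year, the fraction of drug trials in each category.

    Years with zero drug trials are absent from the output (and therefore
    excluded from any downstream regression).
    """
    drug = frame[(frame["included"] == 1) & (frame["trial_class"] == "drug")
                 & frame["drug_category"].ne("")].copy()
    drug["year"] = drug["year"].astype(int)
    counts = (drug.groupby(["year", "drug_category"]).size()
              .unstack(fill_value=0)
              .reindex(columns=list(DRUG_CATEGORIES), fill_value=0))
    totals = counts.sum(axis=1)
    shares = counts.div(totals, axis=0)
    shares["n_drug_trials"] = totals
    return shares.reset_index()


def category_share_trend(frame: pd.DataFrame, category: str) -> TrendFit:
    """Linear trend in a category's share of drug trials.

    Fitted on trial-level 0/1 indicators (is this drug trial in the
    category?) against launch year, matching the convention of running
    trend regressions on raw per-trial values.
    """
    drug = frame[(frame["included"] == 1) & (frame["trial_class"] == "drug")
                 & frame["drug_category"].ne("")]
    years = drug["year"].astype(int).to_numpy()
    indicator = (drug["drug_category"] == category).astype(float).to_numpy()
    return linear_trend(years, indicator)
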