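"""End-to-end orchestration: parse -> screen -> annotate -> audit -> stats.

The pipeline is deterministic given fixed inputs; every output is a tidy
TSV with a one-line ``# schema:`` header comment, plus a JSON run manifest
whose screening counts telescope (each stage no larger than the previous).
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import (DISEASES, DRUG_CATEGORIES, EXCLUSION_REASONS,
                     load_rules, rules_hash)
from .curation import (AnnotatedTrial, annotations_to_frame, assign_stage_window,
                       assign_trial_class, categorize_drug_trial, classify_arms,
                       ContradictoryCues, frame_to_annotations, map_diseases,
                       reassign_soc_placebo, screen_trial,
                       typed_annotation_frame)
from .eligibility import (ScoreWindowError, count_criteria,
                          extract_score_window, select_primary_window)
from .genetics import (category_share_trend, euler_region_counts, mean_lag,
                       support_audit, support_share_by_year,
                       target_sets_from_annotations)
from .registry_io import (LookupTables, TrialRecord, read_lookup_tables,
                          read_records_tsv, read_registry_dir,
                          write_annotation_table, write_manifest)
from .stats import (annualized_counts, duration_years, fisher_enrichment,
                    ks_compare, linear_trend, ordinal_stage_trend,
                    patient_years, share, tabulate, yearly_mean_ci)

log = logging.getLogger("ndtrials")

__all__ = ["annotate_trial", "annotate_records", "run_pipeline",
            "compute_tables", "report_shares", "build_manifest"]


def _other_scale_used(text: str, rules: dict) -> bool:
    low = text.lower()
    return any(tok in low for tok in rules["other_scale_tokens"])


def annotate_trial(record: TrialRecord, lookups: LookupTables, rules: dict,
                   cues: Optional[Sequence[str]] = None) -> AnnotatedTrial:
    """Run one record through classification, screening and annotation."""
    warnings: list[str] = []
    arms = classify_arms(record.arms, lookups, rules)
    diseases = map_diseases(record.conditions, rules)
    year = record.start_date.year if record.start_date else None
    arms = reassign_soc_placebo(arms, lookups, year, diseases)
    record = dataclasses.replace(record, arms=arms)

    decision = screen_trial(record, rules, lookups)
    if not decision.included:
        return AnnotatedTrial(record=record, included=False,
                              exclusion_reason=decision.exclusion_reason)
    warnings.extend(decision.warnings)

    criteria = count_criteria(record.eligibility_text)
    if criteria.method == "manual_override":
        warnings.append("criteria counts need manual review")

    windows = []
    for scale in ("MMSE", "HY"):
        try:
            window = extract_score_window(record.eligibility_text, scale,
                                          rules)
        except ScoreWindowError as exc:
            warnings.append(f"score window rejected: {exc}")
            window = None
        if window is not None:
            windows.append(window)
    try:
        primary = select_primary_window(windows)
    except ScoreWindowError as exc:
        warnings.append(f"score window rejected: {exc}")
        primary = None
    if primary is not None:
        severity_scale = primary.scale
    elif _other_scale_used(record.eligibility_text, rules):
        severity_scale = "other"
    else:
        severity_scale = "none"

    stage_min = stage_max = None
    if cues:
        try:
            stage_min, stage_max = assign_stage_window(cues)
        except ContradictoryCues as exc:
            warnings.append(f"stage cues need manual review: {exc}")

    trial_class, controlled = assign_trial_class(arms, rules)
    if trial_class is None:
        warnings.append("no non-control arm left after classification")

    drug_canonicals: tuple[str, ...] = ()
    category = None
    missing_reason = None
    if trial_class == "drug":
        drug_canonicals = tuple(sorted({
            a.canonical_drug_name for a in arms
            if a.assigned_class == "drug" and a.canonical_drug_name}))
        category, missing_reason = categorize_drug_trial(
            drug_canonicals, diseases, year, lookups)

    return AnnotatedTrial(
        record=record, included=True, diseases=diseases,
        stage_min=stage_min, stage_max=stage_max, criteria=criteria,
        score_window=primary, severity_scale=severity_scale,
        trial_class=trial_class, placebo_soc_controlled=controlled,
        drug_canonicals=drug_canonicals, drug_category=category,
        category_missing_reason=missing_reason,
        duration_years=duration_years(record.start_date,
                                      record.completion_date),
        patient_years=patient_years(record),
        warnings=tuple(warnings),
    )


def annotate_records(records: Sequence[TrialRecord], lookups: LookupTables,
                     rules: dict,
                     cues: Optional[Mapping[str, Sequence[str]]] = None
                     ) -> list[AnnotatedTrial]:
    cues = cues or {}
    out = []
    for record in records:
        trial = annotate_trial(record, lookups, rules,
                               cues.get(record.nct_id))
        if not trial.included:
            log.info("excluded %s: %s", record.nct_id, trial.exclusion_reason)
        out.append(trial)
    return out


def build_manifest(trials: Sequence[AnnotatedTrial], rules: dict,
                   seed: Optional[int] = None,
                   config_hash: Optional[str] = None) -> dict:
    """Screening funnel and provenance. Counts telescope by construction."""
    n_total = len(trials)
    reasons = {r: 0 for r in EXCLUSION_REASONS}
    for t in trials:
        if not t.included:
            reasons[t.exclusion_reason] += 1
    n_included = sum(t.included for t in trials)
    funnel = [n_total]
    remaining = n_total
    for reason in EXCLUSION_REASONS:
        remaining -= reasons[reason]
        funnel.append(remaining)
    assert funnel[-1] == n_included
    return {
        "software_version": __version__,
        "seed": seed,
        "config_hash": config_hash,
        "rules_hash": rules_hash(rules),
        "n_records": n_total,
        "n_included": n_included,
        "exclusions": reasons,
        "screening_funnel": funnel,
    }


# ---------------------------------------------------------------------------
# Statistics tables

_PREVENTIVE_MAX_STAGE = 2      # stages 0-2 = pre-symptomatic/preventive


def compute_tables(frame: pd.DataFrame, lookups: LookupTables,
                   annualization_factor: float = 4.0,
                   partial_year: Optional[int] = 2020) -> dict[str, pd.DataFrame]:
    """All landscape statistics from a typed annotation table.

    Returns a dict of tidy tables: univariate and bivariate tabulations,
    stage-by-year annualized counts, criteria and score-window trend fits,
    the stage ordinal trend, the 7-category breakdown with patient-year
    shares, category share trends, the genetic-support audit, the
    preventive-vs-symptomatic enrichment (Fisher) forest table,
    Kolmogorov-Smirnov comparisons, and headline shares.
    """
    inc = frame[frame["included"] == 1].copy()
    tables: dict[str, pd.DataFrame] = {}

    # -- tabulations ------------------------------------------------------
    uni_parts = []
    for dim in ("disease", "sector", "trial_class", "phase",
                "placebo_soc_controlled", "stage_min"):
        t = tabulate(frame, [dim]).table
        t.insert(0, "dimension", dim)
        t = t.rename(columns={dim: "level"})
        t["level"] = t["level"].astype(str)
        uni_parts.append(t)
    tables["univariate"] = pd.concat(uni_parts, ignore_index=True)

    bi_parts = []
    for dim2 in ("disease", "sector", "phase", "placebo_soc_controlled"):
        t = tabulate(frame, ["trial_class", dim2]).table
        t.insert(0, "dim2", dim2)
        t = t.rename(columns={dim2: "level2", "trial_class": "level1"})
        t.insert(0, "dim1", "trial_class")
        t["level2"] = t["level2"].astype(str)
        bi_parts.append(t)
    tables["bivariate"] = pd.concat(bi_parts, ignore_index=True)

    tables["stage_by_year"] = annualized_counts(
        frame, by="stage_min", factor=annualization_factor,
        partial_year=partial_year)

    # -- criteria trends (industry drug vs all other) --------------------
    inc["industry_drug"] = ((inc["sector"] == "industry")
                            & (inc["trial_class"] == "drug"))
    crit_rows = []
    for label, sub in (("industry_drug", inc[inc["industry_drug"]]),
                       ("other", inc[~inc["industry_drug"]])):
        data = sub.dropna(subset=["criteria_total", "year"])
        if len(data) >= 3 and data["year"].nunique() >= 2:
            fit = linear_trend(data["year"], data["criteria_total"])
            crit_rows.append({
                "group": label, "slope_per_year": fit.slope,
                "p_value": fit.p_value, "n": fit.n,
                "pred_start": fit.pred_start, "pred_end": fit.pred_end,
                "year_start": fit.x_start, "year_end": fit.x_end})
    tables["criteria_trend"] = pd.DataFrame(crit_rows)
    tables["criteria_yearly_mean"] = yearly_mean_ci(
        inc["year"], inc["criteria_total"])

    # -- score-window bound trends (explicit bounds only) -----------------
    win_rows = []
    for scale in ("MMSE", "HY"):
        sub = inc[inc["severity_scale"] == scale]
        for bound, col, flag in (("min", "win_min", "win_min_inferred"),
                                 ("max", "win_max", "win_max_inferred")):
            data = sub[(sub[flag] == 0)].dropna(subset=[col, "year"])
            if len(data) >= 3 and data["year"].nunique() >= 2:
                fit = linear_trend(data["year"], data[col])
                win_rows.append({
                    "scale": scale, "bound": bound,
                    "slope_per_year": fit.slope, "p_value": fit.p_value,
                    "n": fit.n, "pred_start": fit.pred_start,
                    "pred_end": fit.pred_end})
    tables["score_window_trends"] = pd.DataFrame(win_rows)

    # -- ordinal stage trend ----------------------------------------------
    stage_data = inc.dropna(subset=["stage_min", "year"])
    stage_rows = []
    if len(stage_data) and stage_data["stage_min"].nunique() >= 2:
        res = ordinal_stage_trend(stage_data["year"], stage_data["stage_min"])
        stage_rows.append({
            "earlier_stage_log_odds_per_year": res.statistic,
            "p_value": res.p_value, "ci_lo": res.ci[0], "ci_hi": res.ci[1],
            "n": res.n})
    tables["stage_trend"] = pd.DataFrame(stage_rows)

    # -- drug categories ---------------------------------------------------
    drug = inc[inc["trial_class"] == "drug"]
    categorized = drug[drug["drug_category"] != ""]
    cat = categorized.groupby("drug_category").agg(
        n_trials=("nct_id", "size"),
        patient_years=("patient_years", "sum")).reindex(
            list(DRUG_CATEGORIES), fill_value=0).reset_index()
    total_py = cat["patient_years"].sum()
    cat["patient_years_share_pct"] = [
        share(v, total_py) if total_py > 0 else np.nan
        for v in cat["patient_years"]]
    tables["drug_categories"] = cat
    tables["category_share_by_year"] = support_share_by_year(frame)
    trend_rows = []
    for category in DRUG_CATEGORIES:
        try:
            fit = category_share_trend(frame, category)
        except ValueError:
            continue
        trend_rows.append({"drug_category": category,
                           "slope_per_year": fit.slope,
                           "p_value": fit.p_value, "n": fit.n})
    tables["category_share_trends"] = pd.DataFrame(trend_rows)

    # -- genetic support ---------------------------------------------------
    audit = support_audit(frame, lookups)
    tables["genetic_audit"] = audit
    sets = target_sets_from_annotations(frame, lookups)
    regions = euler_region_counts(sets)
    tables["euler_regions"] = pd.DataFrame(
        [{"region": k, "n_genes": v} for k, v in regions.items()])
    tested_pairs = audit[audit["n_trials"] > 0]
    tables["genetic_summary"] = pd.DataFrame([{
        "n_associations": len(lookups.associations),
        "n_supported_pairs_tested": len(tested_pairs),
        "mean_lag_years_pairs": mean_lag(audit, per="pair"),
        "mean_lag_years_targets": mean_lag(audit, per="target"),
    }])

    # -- preventive vs symptomatic enrichment and KS ----------------------
    staged = inc.dropna(subset=["stage_min"])
    preventive = staged["stage_min"] <= _PREVENTIVE_MAX_STAGE
    enr_rows = []
    properties = {
        "industry_sponsored": staged["sector"] == "industry",
        "drug": staged["trial_class"] == "drug",
        "device": staged["trial_class"] == "device",
        "behavioral": staged["trial_class"] == "behavioral",
        "placebo_soc_controlled": staged["placebo_soc_controlled"] == 1,
        "completed": staged["overall_status"] == "Completed",
        "phase_specified": staged["phase"] != "other_unspecified",
    }
    for name, prop in properties.items():
        table = [[int((preventive & prop).sum()),
                  int((preventive & ~prop).sum())],
                 [int((~preventive & prop).sum()),
                  int((~preventive & ~prop).sum())]]
        res = fisher_enrichment(table, compute_ci=True)
        enr_rows.append({
            "property": name, "odds_ratio": res.statistic,
            "p_value": res.p_value,
            "ci_lo": res.ci[0] if res.ci else np.nan,
            "ci_hi": res.ci[1] if res.ci else np.nan,
            "preventive_with": table[0][0],
            "preventive_without": table[0][1],
            "symptomatic_with": table[1][0],
            "symptomatic_without": table[1][1]})
    tables["enrichment"] = pd.DataFrame(enr_rows)

    ks_rows = []
    for name, col in (("duration_years", "duration_years"),
                      ("enrollment", "enrollment_count")):
        a = staged.loc[preventive, col].dropna()
        b = staged.loc[~preventive, col].dropna()
        if len(a) and len(b):
            res = ks_compare(a, b)
            ks_rows.append({"outcome": name, "D": res.statistic,
                            "p_value": res.p_value,
                            "mean_preventive": float(a.mean()),
                            "mean_symptomatic": float(b.mean())})
    tables["ks_tests"] = pd.DataFrame(ks_rows)

    tables["headline_shares"] = report_shares(frame)
    return tables


def report_shares(frame: pd.DataFrame) -> pd.DataFrame:
    """Headline shares, formatted by the mixed rounding convention."""
    inc = frame[frame["included"] == 1]
    n = len(inc)
    staged = inc.dropna(subset=["stage_min"])
    n_staged = len(staged)
    drug = inc[inc["trial_class"] == "drug"]
    total_py = inc["patient_years"].sum()
    industry_drug = inc[(inc["sector"] == "industry")
                        & (inc["trial_class"] == "drug")]
    categorized = drug[drug["drug_category"] != ""]

    rows = []

    def add(metric: str, num: float, den: float) -> None:
        if den and den > 0:
            rows.append({"metric": metric, "numerator": num,
                         "denominator": den, "share_pct": share(num, den)})
        else:
            rows.append({"metric": metric, "numerator": num,
                         "denominator": den, "share_pct": np.nan})

    add("industry_trials", (inc["sector"] == "industry").sum(), n)
    add("drug_trials", len(drug), n)
    add("industry_patient_years",
        inc.loc[inc["sector"] == "industry", "patient_years"].sum(), total_py)
    add("drug_patient_years", drug["patient_years"].sum(), total_py)
    add("industry_drug_patient_years",
        industry_drug["patient_years"].sum(), total_py)
    add("stage4_trials", (staged["stage_min"] == 4).sum(), n_staged)
    add("stage3_trials", (staged["stage_min"] == 3).sum(), n_staged)
    add("presymptomatic_trials",
        (staged["stage_min"] <= _PREVENTIVE_MAX_STAGE).sum(), n_staged)
    add("severity_scale_used", (inc["severity_scale"] != "none").sum(), n)
    add("mmse_used", (inc["severity_scale"] == "MMSE").sum(), n)
    add("hy_used", (inc["severity_scale"] == "HY").sum(), n)
    if len(categorized):
        add("genetically_supported_drug_trials",
            (categorized["drug_category"] == "novel_genetic_support").sum(),
            len(categorized))
    return pd.DataFrame(rows,
                        columns=["metric", "numerator", "denominator",
                                 "share_pct"])


# ---------------------------------------------------------------------------
# File-level pipeline

_SCHEMAS = {
    "annotations": "one row per registry record; derived labels per the "
                   "curation rules; empty cell = missing",
    "univariate": "dimension, level, n_trials, patient_years, intensity",
    "bivariate": "dim1, level1, dim2, level2, n_trials, patient_years, "
                 "intensity",
    "stage_by_year": "year, stage_min, n_trials, trials_per_year "
                     "(final partial year annualized)",
    "criteria_trend": "group, slope_per_year, p_value, n, pred_start, "
                      "pred_end, year_start, year_end (OLS on trial-level "
                      "criteria totals)",
    "criteria_yearly_mean": "year, n, mean, ci_lo, ci_hi (95% CI of mean)",
    "score_window_trends": "scale, bound, slope_per_year, p_value, n, "
                           "pred_start, pred_end (explicit bounds only)",
    "stage_trend": "proportional-odds slope; positive = earlier stages",
    "drug_categories": "drug_category, n_trials, patient_years, "
                       "patient_years_share_pct",
    "category_share_by_year": "year, one share column per category, "
                              "n_drug_trials",
    "category_share_trends": "drug_category, slope_per_year, p_value, n",
    "genetic_audit": "gene, disease, association_year, source, n_trials, "
                     "patient_years, first_trial_year, lag_years",
    "euler_regions": "region, n_genes (exclusive 3-set regions)",
    "genetic_summary": "association counts and mean discovery-to-trial lags",
    "enrichment": "property, odds_ratio (conditional MLE), p_value, 95% CI, "
                  "2x2 counts (preventive stages 0-2 vs symptomatic 3-4)",
    "ks_tests": "outcome, D, p_value, group means",
    "headline_shares": "metric, numerator, denominator, share_pct",
}


def _write_table(frame: pd.DataFrame, path: Path, schema: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# schema: {schema}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class PipelineConfig:
    registry: str | Path                 # XML directory or records TSV
    lookup_dir: str | Path               # drug_map/approvals/targets/associations
    outdir: str | Path
    cues_path: Optional[str | Path] = None
    rules_path: Optional[str | Path] = None
    seed: Optional[int] = None
    annualization_factor: float = 4.0
    partial_final_year: Optional[int] = 2020


def run_pipeline(config: PipelineConfig) -> Path:
    """Run parse -> screen -> annotate -> audit -> statistics to files.

    On failure the partially written outputs are removed (the log remains)
    and the exception propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        rules = load_rules(config.rules_path)
        registry = Path(config.registry)
        if registry.is_dir():
            records = read_registry_dir(registry)
        else:
            records = read_records_tsv(registry)
        lookup_dir = Path(config.lookup_dir)
        lookups = read_lookup_tables(lookup_dir / "drug_map.tsv",
                                     lookup_dir / "approvals.tsv",
                                     lookup_dir / "targets.tsv",
                                     lookup_dir / "associations.tsv")
        cues = {}
        if config.cues_path is not None:
            from .synthetic import read_stage_cues
            cues = read_stage_cues(config.cues_path)

        trials = annotate_records(records, lookups, rules, cues)
        frame = annotations_to_frame(trials)
        path = outdir / "annotations.tsv"
        write_annotation_table(frame, path)
        written.append(path)

        typed = typed_annotation_frame(frame)
        tables = compute_tables(typed, lookups,
                                annualization_factor=config.annualization_factor,
                                partial_year=config.partial_final_year)
        for name, table in tables.items():
            path = outdir / f"{name}.tsv"
            _write_table(table, path, _SCHEMAS[name])
            written.append(path)

        manifest = build_manifest(trials, rules, seed=config.seed)
        path = outdir / "manifest.json"
        write_manifest(manifest, path)
        written.append(path)
        return outdir
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
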