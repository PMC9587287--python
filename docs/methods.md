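# Methods

This note documents the models, rules and conventions implemented in
`ndtrials`, the design choices made where several readings were possible,
and what the synthetic-registry validation does and does not demonstrate.

## Scope and data model

The unit of analysis is a trial registration in a ClinicalTrials.gov-style
XML dialect (or an equivalent TSV mirror): NCT identifier, title, start and
completion dates, enrollment count with its Actual/Anticipated flag, phase,
lead-sponsor class, overall status, condition strings, free-text
eligibility criteria, and intervention arms. Curated knowledge that in the
original workflow required human judgement — drug-name canonicalization,
approval history, drug→target mapping, gene–disease associations with
first-report years, and disease-stage cues — enters as input lookup tables
and sidecars, never as computation. The package computes everything
downstream of those inputs.

Month-precision dates ("April 2005") resolve to the first of the month:
deterministic, and identically biased across the arms of any comparison.
Intervention labels are normalized by lower-casing, stripping characters
outside printable basic Latin, and collapsing repeated whitespace.

## Screening

Records pass a fixed flowchart; the first failing test records the single
exclusion reason:

1. **Launch window** — start date before the window (default 2000) ⇒
   `pre_2000_launch`.
2. **Therapeutic intervention** — all arms classified `none`/`placebo`
   (biomarker sampling, imaging, observation …) ⇒
   `no_therapeutic_intervention`.
3. **Population** — healthy-volunteer flag with no studied-disease
   condition ⇒ `healthy_volunteers_only`; no condition matching the four
   diseases ⇒ `wrong_disease`; caregiver-directed title/conditions ⇒
   `caregiver_targeted`.
4. **Data errors** — missing start date, or a drug trial none of whose
   drug arms matches the trial's own title (the signature of mis-entered
   arms) ⇒ `data_error`.

This ordering makes the manifest's screening funnel telescope exactly;
the test suite asserts the partition on a 10,000-record corrupted registry.
Records with an indeterminate population are included with a warning
rather than silently dropped.

## Intervention classes and trial class

The registry's declared intervention type is ignored (the same
intervention appears under different types). Classes come from a rule
cascade over the normalized label: explicit placebo tokens (incl. standard
of care, normal saline, no treatment) → drug-map hit → behavioral intent
(exercise, diet, adherence …, *even when a device is involved*) →
procedures (surgery, acupuncture, transplants, radiation, care-protocol
changes) → device tokens → non-therapeutic tokens → other. All token
tables live in `config.DEFAULT_RULES`, are YAML-overridable, and are
hashed into the run manifest.

**SOC reassignment.** If a trial has an experimental drug arm and another
arm's drug was already FDA-approved for a disease of the trial by the
launch year, the approved arm is re-counted as a placebo arm. The
operation never changes the arm count and only moves classes toward
placebo.

**Trial class** aggregates arm classes with priority drug > device >
procedure > behavioral > other over non-placebo/non-none arms. The
priority order is a package decision; drug trials are the unit of the
category analyses, so any drug arm makes a drug trial.

## Eligibility criteria

**Counts.** Top-level items in numbered or bulleted lists (`-`, `*`, `•`,
`n.`, `n)`) under the first-level "Inclusion Criteria" / "Exclusion
Criteria" headings. Depth 1 is defined as the minimum bullet indentation
within a section, which makes the count invariant to marker style and
blank-line insertion (property-tested). An absent heading contributes 0;
text with headings but no recognizable list yields *missing* counts
flagged `manual_override` — mirroring registrations that needed hand
counting.

**Score windows.** Lines mentioning a scale synonym (config-extensible:
"MMSE", "mini-mental …", "H&Y", "Hoehn and Yahr" …) are scanned for
comparator phrases: `between a and b`, `a–b`, `a to b`, `≥/≤/>/<`,
`at least`, `no more than`, `x or above/below`. Conjunctive bounds
intersect; strict inequalities tighten by the instrument's smallest step
(1 MMSE point, 0.5 H&Y stage — modified half-stages are accepted);
one-sided windows are completed to the scale limits (MMSE max 30, min 0;
H&Y max 5, min 0) with the inferred side flagged. Contradictory bounds
reject the window with a reason rather than crash. When several scales
appear, MMSE is prioritized over H&Y and same-scale duplicates intersect;
other severity scales (UPDRS, CDR, ALSFRS-R …) are recognized only as
"uses a severity scale" and never parsed — matching the prioritization of
the curation workflow this reimplements.

## Disease stages

Stages follow the cross-disease 0–4 taxonomy: 0 at-risk (genotype, age or
other risk factors), 1 molecular pathology, 2 detectable only on sensitive
tests, 3 mild impairment short of diagnostic criteria, 4 diagnosed.
Free-text inference of stage is out of scope (it was a manual judgement);
the package maps *structured cues* (`diagnosis_required`, `mci_allowed`,
`biomarker_positive_required`, `presymptomatic_carriers`,
`at_risk_age_only`, …) deterministically to a contiguous
(stage_min, stage_max) window, flagging contradictory cue sets for manual
review. Stages 0–2 define the "preventive / pre-symptomatic" stratum used
by the enrichment analyses.

## Drug-trial taxonomy

Seven mutually exclusive categories, assigned by a cascade over the
trial's tested (experimental, post-SOC-reassignment) drugs:

1. drug FDA-approved for a trial disease, launched **before** the approval
   year → `nd_approved_pre_approval`;
2. same, launched at/after approval → `nd_approved_post_approval`;
3. full approval for a *different* studied disease (subtype
   `other_nd_disease`) or any other indication (`other_indication`) →
   `repurposed`;
4. unapproved single entity whose target already has an approved drug for
   some disease → `new_drug_established_target`;
5. combination whose components are all approved drugs or supplements →
   `approved_combination`;
6. otherwise novel, with ≥1 (target gene, trial disease) pair in the
   association table → `novel_genetic_support`;
7. otherwise (including unknown targets) → `novel_no_genetic_support`.

Two deliberate choices. First, "approved" means *full* marketing approval
in any jurisdiction — accelerated-approval-only drugs are experimental.
Second, step 4 applies to non-combination entities only: a combination of
approved drugs would otherwise inherit its components' approved targets
and could never reach step 5, breaking the 7-way partition. Supplements
count as approved for combination purposes; a supplement alone is an
unapproved entity and falls through to the novel branch. Every drug trial
receives exactly one category or an explicit missing reason (unresolvable
drug name, unknown launch year) — asserted at scale in the tests.

## Genetic support

One association year per (gene, disease): the earliest of Mendelian and
GWAS evidence, taken from the input table (locus-to-gene tie-breaking is
curation provenance, encoded in the table, not recomputed). `is_supported`
is monotone in the table. Lags are first-trial year minus association
year; negative lags (trial pre-dates the association, coincidentally) are
permitted and reported. Because whether "mean lag" should average over
target–indication pairs or over targets is ambiguous, both are computed;
the headline number averages over pairs whose first trial followed the
discovery. The Euler audit reports the seven exclusive regions of
{approved-drug targets} × {tested targets} × {genetically supported
targets}; the counts partition the union, so inclusion–exclusion holds
exactly (property-tested).

## Statistics

* **Patient-years** = duration × enrollment, duration in days/365.25;
  only "Actual" enrollment counts (anticipated ⇒ missing, as does a
  missing or negative duration). An admittedly crude investment proxy:
  participants accrue and withdraw gradually.
* **Trend regressions** are OLS on *trial-level* observations (yearly
  means are display-only), with two-sided slope p-values and fitted values
  at the window's first and last observed year. A constant outcome returns
  slope 0 with p = 1.
* **Stage trend** is a proportional-odds logit model fitted by maximum
  likelihood (BFGS, gradient tolerance 1e-8, year centered for numerical
  stability). Sign convention: the reported statistic is the per-year
  log-odds of enrolling earlier stages, so positive = shift toward
  less-affected participants. With two stage levels the model reduces to
  binary logistic regression (verified against an IRLS oracle).
* **Fisher's exact test**: two-sided p by summing hypergeometric
  probabilities ≤ the observed table's; the statistic is the
  conditional-MLE odds ratio; a zero margin reports p = 1 with the odds
  ratio missing. Verified against exhaustive fixed-margin enumeration for
  every 2×2 table with n ≤ 30.
* **Kolmogorov–Smirnov**: two-sample D with the asymptotic two-sided p
  (no normality assumed); D verified against an exhaustive
  ECDF-breakpoint oracle.
* **Yearly means** carry 95% CIs of the mean (±1.96 SEM); single-
  observation years report a missing CI.
* **Shares** use the mixed reporting precision of the source tables —
  nearest integer percent at ≥10%, one decimal below (half-up) — so
  replication tables can be compared by string match.
* **Annualization**: when the registry window ends part-way through a
  year, that year's raw count is multiplied by a configurable factor
  (default 4, for a three-month slice) in per-year series.
* Combined phases (1/2, 2/3) are stored distinctly and map to the lower
  phase in phase-stratified analyses. Multi-disease trials are one
  annotation row but count once per disease in disease tabulations.
* **Score-window bound trends are fitted on explicitly stated bounds
  only**, excluding inferred one-sided completions: imputing the scale
  maximum for every "MMSE ≥ x" trial would mix a constant into the
  outcome and attenuate exactly the drift the model estimates. The
  inferred flags exist to make this selection possible.

No multiple-testing correction is applied (nominal two-sided p-values),
no survival analysis, and loess smoothing — a display device — is not
implemented.

## Synthetic registry generator

The generator emulates the *statistical shape* of the two-decade
landscape so that every pipeline stage can be validated against known
truth. Defaults are the study conditions: 160 launches/year over
2000–2020 with a three-month final year; 38% industry sponsorship; 58%
drug trials (with a behavioral-enriched, drug-depleted mix in
pre-symptomatic trials); stage mix ≈ (0.6, 0.6, 1.5, 7.8, 89.5)% over
stages 0–4 with an ordinal drift of +0.022 log-odds/year toward earlier
stages (≈8% → ≈15% below stage 4 across the window); criteria totals
Poisson around 9 + 0.4·t for industry drug trials and flat 9 otherwise;
MMSE windows drifting 13.6 → 17.7 (min) and 25.6 → 27.6 (max), H&Y
1.6 → 1.2 and 3.8 → 3.1; 15% one-sided windows; enrollment log-normal
with industry drug trials larger and less skewed (~15% enrolling ≤20
vs ~34%; a heavy-tail component confined to other trials so a handful of
giant trials dominates that group's patient-years); 30% anticipated
enrollment; a drug pool of 39 synthetic entities (approved, repurposed,
established-target, combination, supplement, novel ± genetic support,
with synonyms, code names and typos) over a 13-row synthetic gene–disease
association table. Cohort mixture injects each screening-exclusion arm at
a few percent. All names are synthetic stand-ins; no real drug or gene
identifiers are reproduced.

Eligibility text is rendered through a deliberately small template grammar
(bullet styles, comparator phrasings, occasional nested sub-bullets), so
parser failures indicate parser bugs rather than grammar explosion. Stage
cues go to a structured sidecar standing in for manual curation; the
truth sidecar (latent labels + generating parameters) is written
separately and never read by the pipeline. `corrupt_records` injects
labeled data errors — missing start dates, prose-only criteria blocks,
arms inconsistent with the title — to exercise the `data_error` screen.

**What passing tests show, and what they do not.** On clean generated
registries the pipeline recovers the latent labels *exactly*, and across
100 seeds the fitted 95% CIs cover the injected criteria slope, MMSE bound
drifts and ordinal stage drift in ≥90 runs; under zero drift the trend
tests reject at 5% ± 2% over 2,000 replicates. This validates the rule
system and the statistics against the structure the analysis assumes. It
does not validate robustness to real registry prose (free-form criteria
text, negations, cohort sub-structure), to curation disagreement between
humans, or to registry-completeness biases — on real data those remain
manual-review channels, which is why the missing/override flags exist.

## Problem sizes

The shipped analyses and the acceptance script run one default registry
(~3,240 records — the scale of the annotated landscape). The recovery
study uses 100 seeds at 150 trials/year; the calibration study uses 2,000
replicates of a 200-trial registry drawn from the generator's trial-level
model; determinism is asserted on a 10,000-record corrupted registry.
These sizes make the full validation suite run in a few minutes on one
CPU while keeping every Monte-Carlo check at nominal resolution.

## Known limitations

* Criteria counting and window extraction target the registry dialects
  the grammar covers; genuinely free-form registrations fall back to
  missing values with manual-review flags rather than guesses.
* The stage model assumes a contiguous eligible window; exotic cue
  combinations are flagged, not resolved.
* Patient-years ignore staggered accrual and dropout.
* Multi-cohort registrations contribute one score window (sub-cohort
  windows union into the same-scale intersection rule); per-cohort
  windows are not tracked separately.
* The synthetic association table is small (13 pairs); lag statistics on
  it are scale models of the real audit, not estimates of it.
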