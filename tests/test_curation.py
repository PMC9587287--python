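"""Screening flowchart, class assignment, SOC-placebo reassignment, the
7-category drug taxonomy and stage-cue mapping."""
import dataclasses
import datetime as dt
import itertools

import pandas as pd
import pytest

from ndtrials.config import load_rules
from ndtrials.curation import (ContradictoryCues, assign_stage_window,
                               assign_trial_class, categorize_drug_trial,
                               classify_arm, classify_arms, map_diseases,
                               reassign_soc_placebo, screen_trial)
from ndtrials.registry_io import (DrugInfo, InterventionArm, LookupTables,
                                  TrialRecord)


@pytest.fixture(scope="module")
def toy_lookups():
    drug_map = {
        "examplium": "examplium",          # experimental antibody
        "donepezium": "donepezium",        # AD-approved 1996
        "tetrabenzium": "tetrabenzium",    # HD-approved 2008
        "hypertensol": "hypertensol",      # approved for hypertension only
        "accelimab": "accelimab",          # accelerated approval only
        "mysterol": "mysterol",            # unknown target
        "targetib": "targetib",            # target shared with hypertensol
        "combo plus": "combo",
    }
    infos = {
        "examplium": DrugInfo("examplium",
                              target_genes=frozenset({"APPX1"})),
        "donepezium": DrugInfo("donepezium", nd_approval=("AD", 1996),
                               other_approval=True,
                               target_genes=frozenset({"CHEX9"})),
        "tetrabenzium": DrugInfo("tetrabenzium", nd_approval=("HD", 2008),
                                 other_approval=True,
                                 target_genes=frozenset({"VMATX"})),
        "hypertensol": DrugInfo("hypertensol", other_approval=True,
                                other_indication_area="cardiovascular",
                                target_genes=frozenset({"ACEX9"})),
        "accelimab": DrugInfo("accelimab",
                              target_genes=frozenset({"APPX1"})),
        "mysterol": DrugInfo("mysterol"),
        "targetib": DrugInfo("targetib",
                             target_genes=frozenset({"ACEX9"})),
        "combo": DrugInfo("combo",
                          components=("donepezium", "hypertensol")),
    }
    assoc = pd.DataFrame(
        [("APPX1", "AD", 1991, "mendelian", "")],
        columns=["gene", "disease", "year", "source", "l2g_note"])
    return LookupTables(drug_map, infos, assoc)


def arm(label, declared="Other"):
    return InterventionArm(label, declared)


class TestClassifyArm:
    def test_declared_type_is_ignored_for_dbs(self, rules):
        out = classify_arm(arm("Deep Brain Stimulation", "Behavioral"),
                           rules=rules)
        assert out.assigned_class == "device"

    def test_behavioral_intent_wins_over_device_mention(self, rules):
        out = classify_arm(arm("exercise program delivered via tablet device"),
                           rules=rules)
        assert out.assigned_class == "behavioral"

    def test_normal_saline_is_placebo(self, rules):
        assert classify_arm(arm("Normal Saline"),
                            rules=rules).assigned_class == "placebo"

    def test_drug_map_hit_sets_canonical(self, toy_lookups, rules):
        out = classify_arm(arm("Examplium 50 mg"), toy_lookups, rules)
        assert out.assigned_class == "drug"
        assert out.canonical_drug_name == "examplium"

    def test_empty_label_is_none(self, rules):
        assert classify_arm(arm(""), rules=rules).assigned_class == "none"

    def test_blood_draw_is_none(self, rules):
        assert classify_arm(arm("blood draw and biomarker sampling"),
                            rules=rules).assigned_class == "none"

    def test_deterministic_and_case_whitespace_invariant(self, toy_lookups,
                                                         rules):
        variants = ["Acupuncture", "  acupuncture ", "ACUPUNCTURE"]
        classes = {classify_arm(arm(v), toy_lookups, rules).assigned_class
                   for v in variants}
        assert classes == {"procedure"}
        twice = [classify_arm(arm("acupuncture"), toy_lookups,
                              rules).assigned_class for _ in range(2)]
        assert twice[0] == twice[1]


class TestReassignSocPlacebo:
    def test_approved_comparator_becomes_placebo(self, toy_lookups, rules):
        arms = classify_arms([arm("examplium"), arm("donepezium")],
                             toy_lookups, rules)
        out = reassign_soc_placebo(arms, toy_lookups, 2010, ("AD",))
        assert [a.assigned_class for a in out] == ["drug", "placebo"]

    def test_approved_drug_alone_stays_drug(self, toy_lookups, rules):
        arms = classify_arms([arm("donepezium")], toy_lookups, rules)
        out = reassign_soc_placebo(arms, toy_lookups, 2010, ("AD",))
        assert [a.assigned_class for a in out] == ["drug"]

    def test_wrong_indication_approval_not_reassigned(self, toy_lookups,
                                                      rules):
        arms = classify_arms([arm("examplium"), arm("hypertensol")],
                             toy_lookups, rules)
        out = reassign_soc_placebo(arms, toy_lookups, 2010, ("AD",))
        assert [a.assigned_class for a in out] == ["drug", "drug"]

    def test_rule_matches_exhaustive_oracle(self, toy_lookups, rules):
        """Exhaustive check over (comparator, disease, year): the arm is
        reassigned iff its drug holds an approval for a trial disease dated
        no later than the launch year and an experimental co-arm exists."""
        comparators = ["donepezium", "tetrabenzium", "hypertensol"]
        for name, disease, year in itertools.product(
                comparators, ("AD", "PD", "HD"), (1995, 2000, 2008, 2015)):
            arms = classify_arms([arm("examplium"), arm(name)],
                                 toy_lookups, rules)
            out = reassign_soc_placebo(arms, toy_lookups, year, (disease,))
            info = toy_lookups.drug_info[name]
            expected = (info.nd_approval is not None
                        and info.nd_approval[0] == disease
                        and info.nd_approval[1] <= year)
            assert (out[1].assigned_class == "placebo") == expected
            assert len(out) == len(arms)
            # only ever moves classes toward placebo
            assert out[0].assigned_class == "drug"


class TestAssignTrialClass:
    def test_drug_with_placebo(self, rules):
        arms = [dataclasses.replace(arm("a"), assigned_class="drug"),
                dataclasses.replace(arm("b"), assigned_class="placebo")]
        assert assign_trial_class(arms, rules) == ("drug", True)

    def test_priority_order_on_all_pairs(self, rules):
        """Oracle: enumerate all 2-class combinations; the winner is the
        class earliest in the priority order."""
        priority = rules["class_priority"]
        for a, b in itertools.combinations(priority, 2):
            arms = [dataclasses.replace(arm("x"), assigned_class=a),
                    dataclasses.replace(arm("y"), assigned_class=b)]
            expected = min((a, b), key=priority.index)
            assert assign_trial_class(arms, rules)[0] == expected

    def test_single_procedure_uncontrolled(self, rules):
        arms = [dataclasses.replace(arm("x"), assigned_class="procedure")]
        assert assign_trial_class(arms, rules) == ("procedure", False)

    def test_all_placebo_flagged(self, rules):
        arms = [dataclasses.replace(arm("x"), assigned_class="placebo")]
        assert assign_trial_class(arms, rules)[0] is None


def make_record(**kw):
    defaults = dict(
        nct_id="NCT99999999", title="A Study of Examplium in AD",
        start_date=dt.date(2010, 5, 1), enrollment_count=50,
        enrollment_type="actual", phase="2", sponsor_sector="industry",
        overall_status="Completed", conditions=["Alzheimer Disease"],
        eligibility_text="Inclusion Criteria:\n- Diagnosis of AD\n",
        arms=[arm("examplium")])
    defaults.update(kw)
    return TrialRecord(**defaults)


class TestScreenTrial:
    def _screen(self, record, toy_lookups, rules):
        record = dataclasses.replace(
            record, arms=classify_arms(record.arms, toy_lookups, rules))
        return screen_trial(record, rules, toy_lookups)

    def test_all_none_arms_lack_therapeutic_intervention(self, toy_lookups,
                                                         rules):
        record = make_record(arms=[arm("blood draw"), arm("structural mri")])
        decision = self._screen(record, toy_lookups, rules)
        assert decision.exclusion_reason == "no_therapeutic_intervention"

    def test_healthy_volunteers_only(self, toy_lookups, rules):
        record = make_record(conditions=["Healthy Volunteers"],
                             healthy_volunteers=True,
                             arms=[arm("aerobic exercise program")])
        decision = self._screen(record, toy_lookups, rules)
        assert decision.exclusion_reason == "healthy_volunteers_only"

    def test_valid_ad_drug_trial_included(self, toy_lookups, rules):
        decision = self._screen(make_record(), toy_lookups, rules)
        assert decision.included and decision.exclusion_reason is None

    def test_pre_window_launch_excluded_first(self, toy_lookups, rules):
        record = make_record(start_date=dt.date(1998, 1, 1),
                             conditions=["Multiple Sclerosis"])
        decision = self._screen(record, toy_lookups, rules)
        assert decision.exclusion_reason == "pre_2000_launch"

    def test_wrong_disease(self, toy_lookups, rules):
        record = make_record(conditions=["Multiple Sclerosis"],
                             title="A Study of Exercise in MS",
                             arms=[arm("aerobic exercise program")])
        decision = self._screen(record, toy_lookups, rules)
        assert decision.exclusion_reason == "wrong_disease"

    def test_caregiver_targeted(self, toy_lookups, rules):
        record = make_record(
            title="Support Program for Caregivers of Patients With AD",
            arms=[arm("education program")])
        decision = self._screen(record, toy_lookups, rules)
        assert decision.exclusion_reason == "caregiver_targeted"

    def test_missing_start_date_is_data_error(self, toy_lookups, rules):
        record = make_record(start_date=None)
        decision = self._screen(record, toy_lookups, rules)
        assert decision.exclusion_reason == "data_error"

    def test_arm_title_mismatch_is_data_error(self, toy_lookups, rules):
        record = make_record(title="A Study of Mysterol in AD")
        decision = self._screen(record, toy_lookups, rules)
        assert decision.exclusion_reason == "data_error"


class TestCategorizeDrugTrial:
    def test_nd_drug_in_other_nd_disease_is_repurposed(self, toy_lookups):
        category, reason = categorize_drug_trial(
            ["donepezium"], ("PD",), 2010, toy_lookups)
        assert reason is None
        assert category.value == "repurposed"
        assert category.repurposed_subtype == "other_nd_disease"

    def test_accelerated_only_approval_counts_as_experimental(self,
                                                              toy_lookups):
        category, _ = categorize_drug_trial(
            ["accelimab"], ("AD",), 2019, toy_lookups)
        assert category.value == "novel_genetic_support"

    def test_unknown_target_is_novel_without_support(self, toy_lookups):
        category, _ = categorize_drug_trial(
            ["mysterol"], ("AD",), 2010, toy_lookups)
        assert category.value == "novel_no_genetic_support"

    def test_pre_vs_post_approval_split_on_launch_year(self, toy_lookups):
        pre, _ = categorize_drug_trial(["tetrabenzium"], ("HD",), 2005,
                                       toy_lookups)
        post, _ = categorize_drug_trial(["tetrabenzium"], ("HD",), 2008,
                                        toy_lookups)
        assert pre.value == "nd_approved_pre_approval"
        assert post.value == "nd_approved_post_approval"

    def test_established_target_new_drug(self, toy_lookups):
        category, _ = categorize_drug_trial(["targetib"], ("PD",), 2010,
                                            toy_lookups)
        assert category.value == "new_drug_established_target"

    def test_combination_of_approved_components(self, toy_lookups):
        category, _ = categorize_drug_trial(["combo"], ("PD",), 2010,
                                            toy_lookups)
        assert category.value == "approved_combination"

    def test_unresolved_name_gives_missing_reason(self, toy_lookups):
        category, reason = categorize_drug_trial(
            [], ("AD",), 2010, toy_lookups)
        assert category is None and "unresolved" in reason

    def test_every_pool_drug_receives_exactly_one_category(self, lookups):
        """Coverage: each drug in the full synthetic pool gets exactly one
        of the 7 categories (or an explicit missing reason) in each disease."""
        from ndtrials.config import DRUG_CATEGORIES
        for canon in lookups.drug_info:
            for disease in ("AD", "PD", "FTD_ALS", "HD"):
                category, reason = categorize_drug_trial(
                    [canon], (disease,), 2012, lookups)
                assert reason is None
                assert category.value in DRUG_CATEGORIES


class TestAssignStageWindow:
    @pytest.mark.parametrize("cues,expected", [
        ({"diagnosis_required"}, (4, 4)),
        ({"presymptomatic_carriers", "diagnosis_allowed"}, (0, 4)),
        ({"mci_allowed"}, (3, 3)),
        ({"mci_allowed", "diagnosis_allowed"}, (3, 4)),
        ({"biomarker_positive_required", "diagnosis_allowed"}, (1, 4)),
        ({"at_risk_age_only"}, (0, 0)),
    ])
    def test_cue_combinations(self, cues, expected):
        assert assign_stage_window(cues) == expected

    def test_contradictory_cues_flagged(self):
        with pytest.raises(ContradictoryCues):
            assign_stage_window({"diagnosis_required", "mci_allowed"})
        with pytest.raises(ContradictoryCues):
            assign_stage_window({"at_risk_age_only", "diagnosis_allowed"})
        with pytest.raises(ContradictoryCues):
            assign_stage_window(set())


def test_map_diseases_word_boundaries(rules):
    assert map_diseases(["Alzheimer's Disease"], rules) == ("AD",)
    assert map_diseases(["Amyotrophic Lateral Sclerosis",
                         "Parkinson Disease"], rules) == ("PD", "FTD_ALS")
    # 'als' must not fire inside unrelated words
    assert map_diseases(["False Memory Study"], rules) == ()
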