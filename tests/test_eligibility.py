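"""Criteria counting and severity-score window extraction.

The window tests check parsed windows against a brute-force oracle: each
generated phrase carries the predicate it encodes, and membership of every
representable score (integers for MMSE, half-points for H&Y) must agree
between the parsed window and direct evaluation of the predicate.
"""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndtrials.eligibility import (CriteriaCount, ScoreWindowError,
                                  count_criteria, extract_score_window,
                                  select_primary_window, ScoreWindow)

TEXT = """Inclusion Criteria:

- Diagnosis of Parkinson Disease
- Age 40 to 80 years
- Stable medication for 30 days

Exclusion Criteria:

1. Prior brain surgery
2. Pregnancy
"""


class TestCountCriteria:
    def test_counts_bulleted_and_numbered_lists(self):
        count = count_criteria(TEXT)
        assert (count.n_inclusion, count.n_exclusion, count.total) == (3, 2, 5)
        assert count.method == "list_counted"

    def test_prose_only_flags_manual_review(self):
        text = ("Inclusion Criteria:\n\nAdults with a confirmed diagnosis "
                "who can consent.\n\nExclusion Criteria:\n\nAnything else.")
        count = count_criteria(text)
        assert count.n_inclusion is None and count.total is None
        assert count.method == "manual_override"

    def test_nested_sub_bullets_not_counted(self):
        text = ("Inclusion Criteria:\n"
                "- Alpha\n"
                "    - sub one\n"
                "    - sub two\n"
                "- Beta\n"
                "    - sub three\n"
                "    - sub four\n"
                "- Gamma\n")
        # oracle: hand count at depth 1 -> 3 top-level items
        assert count_criteria(text).n_inclusion == 3

    def test_absent_heading_counts_zero_for_that_side(self):
        text = "Inclusion Criteria:\n- Only item\n"
        count = count_criteria(text)
        assert (count.n_inclusion, count.n_exclusion) == (1, 0)

    def test_no_heading_at_all_is_missing(self):
        assert count_criteria("free text only").total is None

    @pytest.mark.parametrize("marker", ["- ", "* ", "• "])
    def test_invariant_to_marker_style_and_blank_lines(self, marker):
        restyled = TEXT.replace("- ", marker).replace("\n-", f"\n{marker[0]}")
        spaced = restyled.replace("\n", "\n\n")
        base = count_criteria(TEXT)
        for variant in (restyled, spaced):
            count = count_criteria(variant)
            assert (count.n_inclusion, count.n_exclusion) == (
                base.n_inclusion, base.n_exclusion)


_ITEM = st.sampled_from([
    "Confirmed diagnosis by a specialist",
    "Stable medication regimen",
    "Able to provide informed consent",
    "Study partner available",
    "No recent surgery",
])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(inc=st.lists(_ITEM, min_size=1, max_size=8),
       exc=st.lists(_ITEM, min_size=0, max_size=8),
       marker=st.sampled_from(["- ", "* ", "• ", "NUM. ", "NUM) "]),
       pad=st.integers(0, 2))
def test_counts_equal_item_list_lengths(inc, exc, marker, pad):
    """Rendering any item lists under the two headings and re-counting
    recovers the list lengths, for every marker style and blank-line
    padding."""
    def render(items):
        lines = []
        for i, item in enumerate(items, start=1):
            lines.append(marker.replace("NUM", str(i)) + item)
            lines.extend([""] * pad)
        return "\n".join(lines)

    text = ("Inclusion Criteria:\n\n" + render(inc)
            + "\n\nExclusion Criteria:\n\n" + render(exc))
    count = count_criteria(text)
    assert count.n_inclusion == len(inc)
    assert count.n_exclusion == len(exc)


class TestExtractScoreWindow:
    def test_one_sided_minimum_infers_scale_maximum(self):
        win = extract_score_window("- MMSE ≥ 20", "MMSE")
        assert (win.min_score, win.max_score) == (20, 30)
        assert win.max_inferred and not win.min_inferred

    def test_explicit_between_bounds(self):
        win = extract_score_window(
            "- Hoehn and Yahr stage between 1 and 3", "HY")
        assert (win.min_score, win.max_score) == (1, 3)
        assert not win.min_inferred and not win.max_inferred

    def test_strict_inequalities_tightened_by_step(self):
        # oracle: integers 0..30 satisfying (>17) & (<27) span 18..26
        satisfying = [s for s in range(31) if 17 < s < 27]
        win = extract_score_window("- MMSE > 17 and < 27", "MMSE")
        assert (win.min_score, win.max_score) == (min(satisfying),
                                                  max(satisfying))

    def test_half_point_hy_strict_step(self):
        win = extract_score_window("- H&Y stage > 0.5 and < 3.5", "HY")
        assert (win.min_score, win.max_score) == (1.0, 3.0)

    def test_no_mention_returns_none(self):
        assert extract_score_window("- Age 40 to 80 years", "MMSE") is None

    def test_contradictory_bounds_rejected(self):
        with pytest.raises(ScoreWindowError):
            extract_score_window("- MMSE >= 25 and <= 10", "MMSE")

    def test_sentence_punctuation_tolerated(self):
        win = extract_score_window("Hoehn & Yahr stage score 1-4.", "HY")
        assert (win.min_score, win.max_score) == (1, 4)

    def test_membership_agrees_with_predicate_oracle(self):
        """Parsed-window membership equals direct predicate evaluation on a
        generated corpus of comparator phrases."""
        rng = np.random.default_rng(20240917)
        cases = []
        for _ in range(150):
            scale = "MMSE" if rng.random() < 0.5 else "HY"
            top, step = (30, 1.0) if scale == "MMSE" else (5, 0.5)
            grid = np.arange(0, top + step / 2, step)
            lo, hi = sorted(rng.choice(grid, size=2, replace=False))
            name = {"MMSE": "MMSE", "HY": "Hoehn and Yahr stage"}[scale]
            kind = rng.integers(4)
            if kind == 0:
                text = f"- {name} score between {lo:g} and {hi:g}"
                pred = lambda s, lo=lo, hi=hi: lo <= s <= hi
            elif kind == 1:
                text = f"- {name} score >= {lo:g} and <= {hi:g}"
                pred = lambda s, lo=lo, hi=hi: lo <= s <= hi
            elif kind == 2:
                text = f"- {name} score of {lo:g} or above"
                pred = lambda s, lo=lo: s >= lo
            else:
                text = f"- {name} score of {hi:g} or below"
                pred = lambda s, hi=hi: s <= hi
            cases.append((scale, text, pred, grid))
        for scale, text, pred, grid in cases:
            win = extract_score_window(text, scale)
            assert win is not None, text
            for s in grid:
                assert win.contains(s) == pred(s), (text, s)

    def test_window_monotone_under_conjunctive_bound(self):
        base = extract_score_window("- MMSE score of 10 or above", "MMSE")
        tightened = extract_score_window(
            "- MMSE score of 10 or above\n- MMSE score of 24 or below",
            "MMSE")
        width = lambda w: w.max_score - w.min_score
        assert width(tightened) <= width(base)


class TestSelectPrimaryWindow:
    def test_mmse_prioritized_over_hy(self):
        hy = ScoreWindow("HY", 1, 3)
        mmse = ScoreWindow("MMSE", 20, 30)
        assert select_primary_window([hy, mmse]) == mmse

    def test_empty_list_gives_none(self):
        assert select_primary_window([]) is None

    def test_same_scale_windows_intersect(self):
        # oracle: intersection of integer ranges [10,26] and [20,30]
        a, b = ScoreWindow("MMSE", 10, 26), ScoreWindow("MMSE", 20, 30)
        merged = select_primary_window([a, b])
        expected = sorted(set(range(10, 27)) & set(range(20, 31)))
        assert (merged.min_score, merged.max_score) == (expected[0],
                                                        expected[-1])

    def test_empty_intersection_rejected(self):
        a, b = ScoreWindow("MMSE", 0, 10), ScoreWindow("MMSE", 20, 30)
        with pytest.raises(ScoreWindowError, match="intersection"):
            select_primary_window([a, b])
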