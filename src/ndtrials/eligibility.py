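"""Eligibility-criteria text analytics.

Two extractions from the free-text "Inclusion Criteria" / "Exclusion
Criteria" block of a trial registration:

* the number of top-level items in numbered or bulleted lists under each
  heading (:func:`count_criteria`), and
* the admissible severity-score window on the Mini-Mental State Examination
  (MMSE, 0-30, lower = more impaired) or the Hoehn & Yahr scale (0-5 with
  modified half-stages, higher = more impaired)
  (:func:`extract_score_window`).

One-sided windows are completed by inference: a stated minimum implies the
scale maximum as the upper bound and vice versa, with the inferred side
flagged. Strict inequalities are tightened by the smallest representable
increment of the instrument (1 MMSE point, 0.5 H&Y stage).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .config import DEFAULT_RULES, SCALE_MAX, SCALE_STEP

__all__ = ["CriteriaCount", "ScoreWindow", "ScoreWindowError",
           "count_criteria", "extract_score_window", "select_primary_window"]


class ScoreWindowError(ValueError):
    """Contradictory or empty score window (min > max after resolution)."""


@dataclass(frozen=True)
class CriteriaCount:
    """Top-level inclusion/exclusion item counts.

    Counts are None (missing) when the text has no recognized list
    structure, in which case ``method`` is ``manual_override`` — mirroring
    registrations whose criteria are prose and must be counted by hand.
    """
    n_inclusion: Optional[int]
    n_exclusion: Optional[int]
    method: str = "list_counted"      # {list_counted, manual_override}

    @property
    def total(self) -> Optional[int]:
        if self.n_inclusion is None or self.n_exclusion is None:
            return None
        return self.n_inclusion + self.n_exclusion


@dataclass(frozen=True)
class ScoreWindow:
    """Admissible severity-score range on one scale."""
    scale: str                  # {MMSE, HY}
    min_score: float
    max_score: float
    min_inferred: bool = False
    max_inferred: bool = False

    def __post_init__(self) -> None:
        if self.min_score > self.max_score:
            raise ScoreWindowError(
                f"{self.scale}: min {self.min_score} > max {self.max_score}")
        if not (0 <= self.min_score and self.max_score <= SCALE_MAX[self.scale]):
            raise ScoreWindowError(
                f"{self.scale}: window [{self.min_score}, {self.max_score}] "
                f"outside scale range")

    def contains(self, score: float) -> bool:
        return self.min_score <= score <= self.max_score


_HEADING_RE = re.compile(
    r"^[^\S\n]*(inclusion|exclusion)\s+criteria\b[^\n]*$",
    re.IGNORECASE | re.MULTILINE)
# Bullet markers at line start: -, *, •, or "n." / "n)" numbering.
_BULLET_RE = re.compile(r"^([ \t]*)(?:[-*•]|\(?\d{1,3}[.)])[ \t]+\S")


def count_criteria(eligibility_text: str) -> CriteriaCount:
    """Count top-level list items under each criteria heading.

    Sections are delimited by "Inclusion Criteria" / "Exclusion Criteria"
    headings; within a section, list items are lines starting with a
    recognized bullet or number marker, and only items at the shallowest
    indentation level (nesting depth 1) are counted. An absent heading
    scores 0 for that side; text with heading(s) but no recognized list at
    all yields missing counts flagged for manual review. Degenerate text
    never raises.
    """
    headings = list(_HEADING_RE.finditer(eligibility_text))
    if not headings:
        return CriteriaCount(None, None, method="manual_override")

    counts = {"inclusion": 0, "exclusion": 0}
    seen_side = {"inclusion": False, "exclusion": False}
    any_bullet = False
    for i, match in enumerate(headings):
        side = match.group(1).lower()
        seen_side[side] = True
        start = match.end()
        end = (headings[i + 1].start() if i + 1 < len(headings)
               else len(eligibility_text))
        bullet_indents = []
        for line in eligibility_text[start:end].splitlines():
            m = _BULLET_RE.match(line)
            if m:
                bullet_indents.append(len(m.group(1).expandtabs()))
        if bullet_indents:
            any_bullet = True
            top = min(bullet_indents)
            counts[side] += sum(1 for ind in bullet_indents if ind == top)

    if not any_bullet:
        return CriteriaCount(None, None, method="manual_override")
    return CriteriaCount(counts["inclusion"], counts["exclusion"],
                         method="list_counted")


# Comparator phrase patterns, applied in order with span masking so that
# e.g. ">=" is consumed before ">" and "no less than" before "less than".
_NUM = r"(\d+(?:\.\d+)?)"
_PATTERNS: list[tuple[str, re.Pattern]] = [
    ("between", re.compile(rf"between\s+{_NUM}\s+and\s+{_NUM}", re.I)),
    ("ge", re.compile(
        rf"(?:≥|>=|=>|at least|no less than|not less than|a minimum (?:score )?of)\s*{_NUM}",
        re.I)),
    ("le", re.compile(
        rf"(?:≤|<=|=<|at most|no more than|not more than|up to|a maximum (?:score )?of)\s*{_NUM}",
        re.I)),
    ("ge", re.compile(
        rf"(?:score of\s+)?{_NUM}\s+or\s+(?:above|higher|greater|more)", re.I)),
    ("le", re.compile(
        rf"(?:score of\s+)?{_NUM}\s+or\s+(?:below|lower|less)", re.I)),
    ("gt", re.compile(rf"(?:>|greater than|above|over|exceeding)\s*{_NUM}", re.I)),
    ("lt", re.compile(rf"(?:<|less than|below|under)\s*{_NUM}", re.I)),
    ("range", re.compile(
        rf"(?<![\d.]){_NUM}\s*(?:[-–—]|to)\s*{_NUM}(?!\.?\d)", re.I)),
]


def _scale_pattern(synonyms: Iterable[str]) -> re.Pattern:
    alts = sorted((re.escape(s) for s in synonyms), key=len, reverse=True)
    return re.compile(r"(?<![a-z0-9])(?:" + "|".join(alts) + r")(?![a-z0-9])",
                      re.IGNORECASE)


def extract_score_window(eligibility_text: str, scale: str,
                         rules: dict | None = None) -> Optional[ScoreWindow]:
    """Extract the admissible window for one scale from criteria text.

    Scans lines mentioning the scale (per the synonym table in the rules
    config) for comparator phrases; conjunctive bounds combine by
    intersection. One-sided windows are completed to the scale limits with
    the inferred flag set. Returns None when the scale is never bounded;
    raises :class:`ScoreWindowError` on contradictory bounds.
    """
    if scale not in SCALE_MAX:
        raise ValueError(f"unsupported scale {scale!r}")
    synonyms = (rules or DEFAULT_RULES)["scale_synonyms"][scale]
    scale_re = _scale_pattern(synonyms)
    step = SCALE_STEP[scale]
    mins: list[float] = []
    maxs: list[float] = []

    for line in eligibility_text.splitlines():
        if not scale_re.search(line):
            continue
        context = scale_re.sub(" ", line)  # mask the mention itself
        taken: list[tuple[int, int]] = []
        for kind, pattern in _PATTERNS:
            for m in pattern.finditer(context):
                if any(m.start() < e and m.end() > s for s, e in taken):
                    continue
                taken.append((m.start(), m.end()))
                if kind in ("between", "range"):
                    lo, hi = float(m.group(1)), float(m.group(2))
                    mins.append(min(lo, hi))
                    maxs.append(max(lo, hi))
                elif kind == "ge":
                    mins.append(float(m.group(1)))
                elif kind == "le":
                    maxs.append(float(m.group(1)))
                elif kind == "gt":
                    mins.append(float(m.group(1)) + step)
                elif kind == "lt":
                    maxs.append(float(m.group(1)) - step)

    if not mins and not maxs:
        return None
    min_inferred = not mins
    max_inferred = not maxs
    min_score = max(mins) if mins else 0.0
    max_score = min(maxs) if maxs else SCALE_MAX[scale]
    # Clamp explicit bounds into the instrument's range before validation.
    min_score = min(max(min_score, 0.0), SCALE_MAX[scale])
    max_score = min(max(max_score, 0.0), SCALE_MAX[scale])
    return ScoreWindow(scale, min_score, max_score,
                       min_inferred=min_inferred, max_inferred=max_inferred)


def select_primary_window(
        windows: Sequence[ScoreWindow]) -> Optional[ScoreWindow]:
    """Pick one window per trial, prioritizing MMSE over Hoehn & Yahr.

    When several windows exist on the chosen scale, their intersection is
    returned; an empty intersection raises :class:`ScoreWindowError`.
    """
    for scale in ("MMSE", "HY"):
        same = [w for w in windows if w.scale == scale]
        if not same:
            continue
        min_score = max(w.min_score for w in same)
        max_score = min(w.max_score for w in same)
        if min_score > max_score:
            raise ScoreWindowError(
                f"{scale}: empty intersection of {len(same)} windows")
        min_inferred = all(w.min_inferred for w in same
                           if w.min_score == min_score)
        max_inferred = all(w.max_inferred for w in same
                           if w.max_score == max_score)
        return ScoreWindow(scale, min_score, max_score,
                           min_inferred=min_inferred,
                           max_inferred=max_inferred)
    return None
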