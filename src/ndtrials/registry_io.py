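"""Reading and writing trial registration records and curated lookup tables.

Two equivalent encodings of a trial registration are supported: a
ClinicalTrials.gov-style XML dialect (one ``<clinical_study>`` element per
record) and a flat TSV mirror. Curated knowledge enters through four TSV
lookup tables: a drug canonicalization map (synonym -> canonical name), a
drug approval table, a drug -> target-gene map, and a gene-disease
association table. All downstream modules consume only the domain types
defined here.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from lxml import etree

from .config import DISEASES, PHASES

__all__ = [
    "InterventionArm", "TrialRecord", "DrugInfo", "LookupTables",
    "RegistryParseError", "RecordRejected", "LookupValidationError",
    "normalize_label", "parse_registry_record", "record_to_xml",
    "read_registry_dir", "write_registry_dir",
    "records_to_frame", "frame_to_records",
    "write_records_tsv", "read_records_tsv",
    "read_lookup_tables", "write_lookup_tables",
    "write_annotation_table", "read_annotation_table", "write_manifest",
]


class RegistryParseError(ValueError):
    """Malformed XML or an unparseable field value."""


class RecordRejected(ValueError):
    """A structurally valid record that cannot be admitted (e.g. no NCT id)."""


class LookupValidationError(ValueError):
    """Cross-reference or uniqueness failure in the curated lookup tables."""


# Invalid-character stripping: printable basic Latin only, whitespace
# collapsed. Applied to intervention labels before any rule matching.
_NON_PRINTABLE = re.compile(r"[^\x20-\x7e]+")
_WS = re.compile(r"\s+")


def normalize_label(raw: str) -> str:
    """Lower-case a label and strip invalid text characters.

    Characters outside printable basic Latin are removed and repeated
    whitespace is collapsed, so that the same intervention registered with
    different casing, unicode dashes or stray control characters yields one
    unique value for curation.
    """
    text = _NON_PRINTABLE.sub(" ", raw.lower())
    return _WS.sub(" ", text).strip()


@dataclass
class InterventionArm:
    """One intervention arm of a trial.

    ``declared_type`` is the registry-provided type string, which is
    unreliable and ignored by classification; ``assigned_class`` is set by
    the curation engine.
    """
    raw_label: str
    declared_type: str = ""
    normalized_label: str = ""
    assigned_class: Optional[str] = None
    canonical_drug_name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.normalized_label:
            self.normalized_label = normalize_label(self.raw_label)


_MONTH_DAY_YEAR = "%B %d, %Y"
_MONTH_YEAR = "%B %Y"


def _parse_ct_date(text: str) -> tuple[dt.date, bool]:
    """Parse a registry date; returns (date, month_precision).

    Month-precision dates ("April 2005") resolve to the first day of the
    month — deterministic and identically biased across any comparison.
    """
    text = text.strip()
    for fmt, month_only in ((_MONTH_DAY_YEAR, False), ("%Y-%m-%d", False),
                            (_MONTH_YEAR, True)):
        try:
            return dt.datetime.strptime(text, fmt).date(), month_only
        except ValueError:
            continue
    raise RegistryParseError(f"unparseable date {text!r}")


def _format_ct_date(date: dt.date, month_precision: bool) -> str:
    if month_precision:
        return date.strftime(_MONTH_YEAR)
    return f"{date.strftime('%B')} {date.day}, {date.year}"


_PHASE_FROM_XML = {
    "Phase 1": "1", "Phase 2": "2", "Phase 3": "3", "Phase 4": "4",
    "Phase 1/Phase 2": "1/2", "Phase 2/Phase 3": "2/3",
    "N/A": "other_unspecified", "": "other_unspecified",
}
_PHASE_TO_XML = {v: k for k, v in _PHASE_FROM_XML.items() if k != ""}


@dataclass
class TrialRecord:
    """One raw trial registration (pre-curation)."""
    nct_id: str
    title: str = ""
    start_date: Optional[dt.date] = None
    start_date_month_precision: bool = False
    completion_date: Optional[dt.date] = None
    completion_date_month_precision: bool = False
    enrollment_count: Optional[int] = None
    enrollment_type: str = "anticipated"      # {actual, anticipated}
    phase: str = "other_unspecified"
    sponsor_sector: str = "other"             # {industry, other}
    overall_status: str = ""
    conditions: list[str] = field(default_factory=list)
    eligibility_text: str = ""
    healthy_volunteers: bool = False
    arms: list[InterventionArm] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise RegistryParseError(f"{self.nct_id}: unknown phase {self.phase!r}")
        if self.enrollment_count is not None and self.enrollment_count < 0:
            raise RegistryParseError(f"{self.nct_id}: negative enrollment")
        if self.enrollment_type not in ("actual", "anticipated"):
            raise RegistryParseError(
                f"{self.nct_id}: unknown enrollment type {self.enrollment_type!r}")


def parse_registry_record(xml_text: str | bytes) -> TrialRecord:
    """Parse a single ``<clinical_study>`` record.

    Raises :class:`RegistryParseError` for malformed XML or field values and
    :class:`RecordRejected` when the record carries no NCT identifier.
    """
    try:
        root = etree.fromstring(
            xml_text.encode() if isinstance(xml_text, str) else xml_text)
    except etree.XMLSyntaxError as exc:
        raise RegistryParseError(f"malformed XML: {exc}") from exc
    if root.tag != "clinical_study":
        raise RegistryParseError(f"unexpected root element <{root.tag}>")

    nct_id = (root.findtext("id_info/nct_id") or "").strip()
    if not nct_id:
        raise RecordRejected("record rejected: missing nct_id")

    def text(path: str) -> str:
        return (root.findtext(path) or "").strip()

    start_date, start_mp = (None, False)
    if text("start_date"):
        start_date, start_mp = _parse_ct_date(text("start_date"))
    completion_date, completion_mp = (None, False)
    if text("completion_date"):
        completion_date, completion_mp = _parse_ct_date(text("completion_date"))

    enrollment_count: Optional[int] = None
    enrollment_type = "anticipated"
    enr = root.find("enrollment")
    if enr is not None and (enr.text or "").strip():
        try:
            enrollment_count = int(enr.text.strip())
        except ValueError as exc:
            raise RegistryParseError(
                f"{nct_id}: bad <enrollment> value {enr.text!r}") from exc
        enrollment_type = (enr.get("type") or "Anticipated").strip().lower()

    phase_text = text("phase")
    if phase_text not in _PHASE_FROM_XML:
        raise RegistryParseError(f"{nct_id}: unknown <phase> {phase_text!r}")

    agency_class = text("sponsors/lead_sponsor/agency_class")
    sector = "industry" if agency_class.lower() == "industry" else "other"

    conditions = [
        (c.text or "").strip() for c in root.findall("condition")
        if (c.text or "").strip()
    ]
    arms = [
        InterventionArm(
            raw_label=(iv.findtext("intervention_name") or "").strip(),
            declared_type=(iv.findtext("intervention_type") or "").strip(),
        )
        for iv in root.findall("intervention")
    ]
    healthy = text("eligibility/healthy_volunteers").lower() in ("yes", "true")

    return TrialRecord(
        nct_id=nct_id,
        title=text("brief_title"),
        start_date=start_date,
        start_date_month_precision=start_mp,
        completion_date=completion_date,
        completion_date_month_precision=completion_mp,
        enrollment_count=enrollment_count,
        enrollment_type=enrollment_type,
        phase=_PHASE_FROM_XML[phase_text],
        sponsor_sector=sector,
        overall_status=text("overall_status"),
        conditions=conditions,
        eligibility_text=root.findtext("eligibility/criteria/textblock") or "",
        healthy_volunteers=healthy,
        arms=arms,
    )


def record_to_xml(record: TrialRecord) -> str:
    """Serialize a record back to the XML dialect (inverse of parsing)."""
    root = etree.Element("clinical_study")
    id_info = etree.SubElement(root, "id_info")
    etree.SubElement(id_info, "nct_id").text = record.nct_id
    etree.SubElement(root, "brief_title").text = record.title
    if record.start_date is not None:
        etree.SubElement(root, "start_date").text = _format_ct_date(
            record.start_date, record.start_date_month_precision)
    if record.completion_date is not None:
        etree.SubElement(root, "completion_date").text = _format_ct_date(
            record.completion_date, record.completion_date_month_precision)
    if record.enrollment_count is not None:
        enr = etree.SubElement(root, "enrollment")
        enr.text = str(record.enrollment_count)
        enr.set("type", record.enrollment_type.capitalize())
    etree.SubElement(root, "phase").text = _PHASE_TO_XML[record.phase]
    sponsors = etree.SubElement(root, "sponsors")
    lead = etree.SubElement(sponsors, "lead_sponsor")
    etree.SubElement(lead, "agency_class").text = (
        "Industry" if record.sponsor_sector == "industry" else "Other")
    etree.SubElement(root, "overall_status").text = record.overall_status
    for cond in record.conditions:
        etree.SubElement(root, "condition").text = cond
    elig = etree.SubElement(root, "eligibility")
    crit = etree.SubElement(elig, "criteria")
    etree.SubElement(crit, "textblock").text = record.eligibility_text
    etree.SubElement(elig, "healthy_volunteers").text = (
        "Yes" if record.healthy_volunteers else "No")
    for arm in record.arms:
        iv = etree.SubElement(root, "intervention")
        etree.SubElement(iv, "intervention_type").text = arm.declared_type
        etree.SubElement(iv, "intervention_name").text = arm.raw_label
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def write_registry_dir(records: Sequence[TrialRecord], outdir: str | Path) -> None:
    """Write one XML file per record under ``outdir`` (named by NCT id)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for record in records:
        (outdir / f"{record.nct_id}.xml").write_text(record_to_xml(record))


def read_registry_dir(indir: str | Path) -> list[TrialRecord]:
    """Read every ``*.xml`` record under a directory, sorted by filename.

    Duplicate NCT ids within the collection are rejected.
    """
    records = []
    seen: set[str] = set()
    for path in sorted(Path(indir).glob("*.xml")):
        record = parse_registry_record(path.read_bytes())
        if record.nct_id in seen:
            raise RecordRejected(f"duplicate nct_id {record.nct_id}")
        seen.add(record.nct_id)
        records.append(record)
    return records


# ---------------------------------------------------------------------------
# TSV mirror of registry records

_RECORD_COLUMNS = [
    "nct_id", "title", "start_date", "start_date_month_precision",
    "completion_date", "completion_date_month_precision",
    "enrollment_count", "enrollment_type", "phase", "sponsor_sector",
    "overall_status", "conditions", "eligibility_text",
    "healthy_volunteers", "arms",
]


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "nct_id": r.nct_id,
            "title": r.title,
            "start_date": r.start_date.isoformat() if r.start_date else "",
            "start_date_month_precision": int(r.start_date_month_precision),
            "completion_date": (r.completion_date.isoformat()
                                if r.completion_date else ""),
            "completion_date_month_precision": int(r.completion_date_month_precision),
            "enrollment_count": ("" if r.enrollment_count is None
                                 else r.enrollment_count),
            "enrollment_type": r.enrollment_type,
            "phase": r.phase,
            "sponsor_sector": r.sponsor_sector,
            "overall_status": r.overall_status,
            "conditions": json.dumps(r.conditions),
            "eligibility_text": json.dumps(r.eligibility_text),
            "healthy_volunteers": int(r.healthy_volunteers),
            "arms": json.dumps([[a.raw_label, a.declared_type] for a in r.arms]),
        })
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(TrialRecord(
            nct_id=row.nct_id,
            title=row.title,
            start_date=(dt.date.fromisoformat(row.start_date)
                        if row.start_date else None),
            start_date_month_precision=bool(int(row.start_date_month_precision)),
            completion_date=(dt.date.fromisoformat(row.completion_date)
                             if row.completion_date else None),
            completion_date_month_precision=bool(
                int(row.completion_date_month_precision)),
            enrollment_count=(None if row.enrollment_count == ""
                              else int(row.enrollment_count)),
            enrollment_type=row.enrollment_type,
            phase=row.phase,
            sponsor_sector=row.sponsor_sector,
            overall_status=row.overall_status,
            conditions=json.loads(row.conditions),
            eligibility_text=json.loads(row.eligibility_text),
            healthy_volunteers=bool(int(row.healthy_volunteers)),
            arms=[InterventionArm(raw_label=a, declared_type=b)
                  for a, b in json.loads(row.arms)],
        ))
    return records


def write_records_tsv(records: Sequence[TrialRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records_tsv(path: str | Path) -> list[TrialRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return frame_to_records(frame)


# ---------------------------------------------------------------------------
# Curated lookup tables

@dataclass(frozen=True)
class DrugInfo:
    """Curated facts about one canonical molecular entity.

    ``nd_approval`` is the (disease, year) of first FDA full approval in one
    of the four studied diseases, if any. ``other_approval`` means full
    marketing approval in any jurisdiction for any indication (implied by
    ``nd_approval``); accelerated-approval-only drugs have it False and are
    treated as experimental. Combinations carry their component canonical
    names; an empty ``target_genes`` set means the target is unknown.
    """
    canonical_name: str
    target_genes: frozenset[str] = frozenset()
    nd_approval: Optional[tuple[str, int]] = None
    other_approval: bool = False
    other_indication_area: Optional[str] = None
    supplement_flag: bool = False
    target_evidence_source: Optional[str] = None
    components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.nd_approval is not None and not self.other_approval:
            raise LookupValidationError(
                f"{self.canonical_name}: nd_approval implies other_approval")


_GENE_RE = re.compile(r"^[A-Z][A-Z0-9-]*$")
# Dose/formulation noise stripped from arm labels before drug-map lookup.
_DOSE_TOKENS = re.compile(
    r"\b(\d+(\.\d+)?\s*(mg|mcg|g|ml|iu)(\s*/\s*(kg|day|ml))?|oral|tablets?|"
    r"capsules?|injection|infusion|extended release|xr|er|once daily|daily|"
    r"weekly|low dose|high dose|dose)\b")


class LookupTables:
    """The four curated lookup tables plus derived indexes.

    Validated at load time: unique synonym keys, unique (gene, disease)
    association pairs, gene-symbol format, and referential integrity
    (every canonical name in the approval/target tables must exist in the
    drug map).
    """

    def __init__(self, drug_map: Mapping[str, str],
                 drug_info: Mapping[str, DrugInfo],
                 associations: pd.DataFrame) -> None:
        self.drug_map = dict(drug_map)          # normalized synonym -> canonical
        self.drug_info = dict(drug_info)        # canonical -> DrugInfo
        self.associations = associations.reset_index(drop=True)
        self._validate()
        self._synonyms_by_len = sorted(
            self.drug_map, key=len, reverse=True)
        self._syn_patterns = {
            syn: re.compile(r"(?<![a-z0-9])" + re.escape(syn) + r"(?![a-z0-9])")
            for syn in self._synonyms_by_len
        }
        self._canon_cache: dict[str, Optional[str]] = {}

    def _validate(self) -> None:
        problems = []
        canonicals = set(self.drug_info)
        for syn, canon in self.drug_map.items():
            if canon not in canonicals:
                problems.append(f"synonym {syn!r} -> unknown canonical {canon!r}")
        for canon, info in self.drug_info.items():
            for gene in info.target_genes:
                if not _GENE_RE.match(gene):
                    problems.append(f"{canon}: bad gene symbol {gene!r}")
            for comp in info.components:
                if comp not in canonicals:
                    problems.append(f"{canon}: unknown component {comp!r}")
        if len(self.associations):
            dup = self.associations.duplicated(["gene", "disease"])
            for _, row in self.associations[dup].iterrows():
                problems.append(
                    f"duplicate association ({row.gene}, {row.disease})")
            for gene in self.associations["gene"]:
                if not _GENE_RE.match(str(gene)):
                    problems.append(f"association: bad gene symbol {gene!r}")
            bad_disease = ~self.associations["disease"].isin(DISEASES)
            for _, row in self.associations[bad_disease].iterrows():
                problems.append(f"association: unknown disease {row.disease!r}")
        if problems:
            raise LookupValidationError(
                "lookup validation failed: " + "; ".join(problems))

    def canonicalize(self, label: str) -> Optional[str]:
        """Resolve a normalized intervention label to a canonical drug name.

        Tries an exact synonym match, then an exact match after stripping
        dose/formulation noise, then the longest synonym occurring as a
        token-bounded substring. Returns None when no synonym matches.
        """
        label = normalize_label(label)
        if label in self._canon_cache:
            return self._canon_cache[label]
        result = self.drug_map.get(label)
        if result is None:
            stripped = _WS.sub(" ", _DOSE_TOKENS.sub(" ", label)).strip(" ,;-")
            result = self.drug_map.get(stripped)
        if result is None:
            for syn in self._synonyms_by_len:
                if self._syn_patterns[syn].search(label):
                    result = self.drug_map[syn]
                    break
        self._canon_cache[label] = result
        return result

    def label_matches_canonical(self, text: str, canonical: str) -> bool:
        """True if any synonym of ``canonical`` occurs in ``text``."""
        text = normalize_label(text)
        return any(self._syn_patterns[syn].search(text)
                   for syn, canon in self.drug_map.items()
                   if canon == canonical)

    @property
    def approved_target_genes(self) -> frozenset[str]:
        """Targets of drugs with full marketing approval for any indication."""
        genes: set[str] = set()
        for info in self.drug_info.values():
            if info.other_approval:
                genes |= info.target_genes
        return frozenset(genes)


def read_lookup_tables(drug_map_path: str | Path,
                       approvals_path: str | Path,
                       targets_path: str | Path,
                       associations_path: str | Path) -> LookupTables:
    """Load and cross-validate the four curated TSV lookup tables.

    Expected headers: drug map ``synonym/canonical_name/supplement/components``;
    approvals ``canonical_name/indication/jurisdiction/year/approval_type``;
    targets ``canonical_name/gene/evidence_source``; associations
    ``gene/disease/year/source/l2g_note``.
    """
    read = lambda p: pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    dm = read(drug_map_path)
    approvals = read(approvals_path)
    targets = read(targets_path)
    associations = read(associations_path)

    problems = []
    drug_map: dict[str, str] = {}
    supplements: set[str] = set()
    components: dict[str, tuple[str, ...]] = {}
    for row in dm.itertuples(index=False):
        syn = normalize_label(row.synonym)
        if syn in drug_map:
            problems.append(f"duplicate synonym {syn!r}")
        drug_map[syn] = row.canonical_name
        if str(getattr(row, "supplement", "0")) in ("1", "true", "True"):
            supplements.add(row.canonical_name)
        comps = str(getattr(row, "components", "")).strip()
        if comps:
            components[row.canonical_name] = tuple(comps.split(";"))
    canonicals = set(drug_map.values())

    for name, tbl in (("approvals", approvals), ("targets", targets)):
        unknown = set(tbl["canonical_name"]) - canonicals
        if unknown:
            problems.append(f"{name}: canonical names missing from drug map: "
                            + ", ".join(sorted(unknown)))
    if problems:
        raise LookupValidationError("lookup validation failed: "
                                    + "; ".join(problems))

    target_genes: dict[str, set[str]] = {}
    evidence: dict[str, str] = {}
    for row in targets.itertuples(index=False):
        target_genes.setdefault(row.canonical_name, set()).add(row.gene)
        evidence.setdefault(row.canonical_name, row.evidence_source)

    nd_approval: dict[str, tuple[str, int]] = {}
    other_approval: set[str] = set()
    other_area: dict[str, str] = {}
    for row in approvals.itertuples(index=False):
        if row.approval_type != "full":
            continue  # accelerated approvals do not confer approved status
        year = int(row.year)
        other_approval.add(row.canonical_name)
        if row.indication in DISEASES and row.jurisdiction == "FDA":
            prev = nd_approval.get(row.canonical_name)
            if prev is None or year < prev[1]:
                nd_approval[row.canonical_name] = (row.indication, year)
        else:
            other_area.setdefault(row.canonical_name, row.indication)

    drug_info = {
        canon: DrugInfo(
            canonical_name=canon,
            target_genes=frozenset(target_genes.get(canon, ())),
            nd_approval=nd_approval.get(canon),
            other_approval=canon in other_approval,
            other_indication_area=other_area.get(canon),
            supplement_flag=canon in supplements,
            target_evidence_source=evidence.get(canon),
            components=components.get(canon, ()),
        )
        for canon in sorted(canonicals)
    }
    if len(associations):
        associations = associations.astype({"year": int}, errors="ignore")
        associations["year"] = associations["year"].astype(int)
    else:
        associations = pd.DataFrame(
            columns=["gene", "disease", "year", "source", "l2g_note"])
    return LookupTables(drug_map, drug_info, associations)


def write_lookup_tables(lookups: LookupTables, outdir: str | Path) -> dict[str, Path]:
    """Write the four lookup tables as TSV; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / f"{k}.tsv"
             for k in ("drug_map", "approvals", "targets", "associations")}

    dm_rows = [
        {"synonym": syn, "canonical_name": canon,
         "supplement": int(lookups.drug_info[canon].supplement_flag),
         "components": ";".join(lookups.drug_info[canon].components)}
        for syn, canon in lookups.drug_map.items()
    ]
    pd.DataFrame(dm_rows).to_csv(paths["drug_map"], sep="\t", index=False)

    appr_rows, target_rows = [], []
    for canon, info in lookups.drug_info.items():
        if info.nd_approval:
            appr_rows.append({"canonical_name": canon,
                              "indication": info.nd_approval[0],
                              "jurisdiction": "FDA",
                              "year": info.nd_approval[1],
                              "approval_type": "full"})
        if info.other_approval and info.other_indication_area:
            appr_rows.append({"canonical_name": canon,
                              "indication": info.other_indication_area,
                              "jurisdiction": "FDA",
                              "year": 1990, "approval_type": "full"})
        for gene in sorted(info.target_genes):
            target_rows.append({"canonical_name": canon, "gene": gene,
                                "evidence_source":
                                    info.target_evidence_source or "other"})
    pd.DataFrame(appr_rows, columns=["canonical_name", "indication",
                                     "jurisdiction", "year", "approval_type"]
                 ).to_csv(paths["approvals"], sep="\t", index=False)
    pd.DataFrame(target_rows, columns=["canonical_name", "gene",
                                       "evidence_source"]
                 ).to_csv(paths["targets"], sep="\t", index=False)
    lookups.associations.to_csv(paths["associations"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Annotation table and manifest I/O

def write_annotation_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write an annotation table as TSV (UTF-8, header row, ISO dates).

    Missing values are written as empty cells, never as zero.
    """
    frame.to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read an annotation table written by :func:`write_annotation_table`."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
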