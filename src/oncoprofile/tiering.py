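"""Clinical actionability tiering of genomic alterations.

Each annotated alteration (somatic or germline) is matched against a frozen
local therapy knowledge base and assigned a tier:

* tier 1 — established clinical utility for that patient's cancer type
  (FDA-approved benefit or resistance in the indication, a pathogenic germline
  variant conferring cancer risk, or a diagnosis-changing marker);
* tier 2 — rationale for investigational or off-label targeted therapy, or
  resistance postulated from strong preclinical evidence;
* tier 3 — implicated in cancer biology but without current therapeutic
  implications.

Subcategories mark the nature of the call: G germline, D diagnosis change,
S somatic therapy rationale, R resistance. A tier-1 germline call whose gene
is itself a therapeutic target carries the ``germline_therapeutic_flag``
(the "G1*" mark on clinical reports).

The knowledge base is a static file with explicit evidence levels rather than
a live database query: public variant-annotation databases drift over time,
and reproducible tiering requires a frozen snapshot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

# Alteration classes observed in integrative DNA+RNA profiling.
ALT_CLASSES = frozenset(
    {
        "mutation",
        "amplification",
        "homozygous_deletion",
        "fusion",
        "outlier_expression",
        "viral",
        "diagnosis_marker",
        "loh",
    }
)

EVIDENCE_LEVELS = (
    "BIOLOGICAL_ONLY",
    "PRECLINICAL_RESISTANCE",
    "INVESTIGATIONAL_OR_OFF_LABEL",
    "FDA_APPROVED_RESISTANCE",
    "FDA_APPROVED_BENEFIT",
)

GERMLINE_RISK_LEVELS = (
    "HIGH_PENETRANT",
    "MODERATE_PENETRANT",
    "AR_CANCER_RISK",
    "AR_NONCANCER",
    "NONE",
)

#: germline_risk values that justify a tier-1 G call
_CANCER_RISK = frozenset({"HIGH_PENETRANT", "MODERATE_PENETRANT", "AR_CANCER_RISK"})

ANY = "ANY"

#: priority of subcategories when several rules tie on tier
_SUBCAT_ORDER = {"G": 0, "D": 1, "S": 2, "R": 3}


class ValidationError(ValueError):
    """Raised for malformed domain records."""


@dataclass(frozen=True)
class Alteration:
    """One somatic or germline event in one patient's tumor profile."""

    patient_id: str
    gene: str
    alt_class: str
    origin: str  # "somatic" | "germline"
    pathogenicity: str | None = None  # pathogenic | likely_pathogenic | other
    cancer_type: str = ANY

    def __post_init__(self) -> None:
        if self.alt_class not in ALT_CLASSES:
            raise ValidationError(f"unknown alteration class {self.alt_class!r}")
        if self.origin not in ("somatic", "germline"):
            raise ValidationError(f"origin must be somatic or germline, got {self.origin!r}")
        if self.origin == "germline":
            if self.alt_class != "mutation":
                raise ValidationError("germline origin is only valid for mutations")
            if self.pathogenicity is None:
                raise ValidationError("germline records require a pathogenicity call")


@dataclass(frozen=True)
class KnowledgeBaseEntry:
    """One gene–alteration–context rule with its evidence level."""

    entry_id: str
    gene: str
    alt_pattern: str  # an alteration class or ANY
    context: str  # cancer-type label or ANY
    evidence: str = "BIOLOGICAL_ONLY"
    germline_risk: str = "NONE"
    germline_therapeutic: bool = False

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValidationError(f"unknown evidence level {self.evidence!r}")
        if self.germline_risk not in GERMLINE_RISK_LEVELS:
            raise ValidationError(f"unknown germline risk level {self.germline_risk!r}")
        if self.alt_pattern != ANY and self.alt_pattern not in ALT_CLASSES:
            raise ValidationError(f"unknown alt_pattern {self.alt_pattern!r}")

    def matches_class(self, alt_class: str) -> bool:
        return self.alt_pattern == ANY or self.alt_pattern == alt_class

    def matches_context(self, cancer_type: str) -> bool:
        return self.context == ANY or self.context == cancer_type


@dataclass(frozen=True)
class TierAssignment:
    tier: int  # 1 | 2 | 3
    subcategory: str  # G | S | R | D
    germline_therapeutic_flag: bool = False
    rationale: KnowledgeBaseEntry | None = None

    def __post_init__(self) -> None:
        if self.tier not in (1, 2, 3):
            raise ValidationError(f"tier must be 1, 2 or 3, got {self.tier}")
        if self.subcategory not in _SUBCAT_ORDER:
            raise ValidationError(f"unknown subcategory {self.subcategory!r}")
        if self.subcategory == "D" and self.tier != 1:
            raise ValidationError("diagnosis-change calls are tier 1 by definition")
        if self.germline_therapeutic_flag and not (self.tier == 1 and self.subcategory == "G"):
            raise ValidationError("the G1* flag applies only to tier-1 germline calls")

    @property
    def actionable(self) -> bool:
        return self.tier in (1, 2)

    def sort_key(self) -> tuple:
        rid = self.rationale.entry_id if self.rationale is not None else "￿"
        return (self.tier, _SUBCAT_ORDER[self.subcategory], rid)


class KnowledgeBase:
    """An in-memory set of tiering rules, loadable from TSV or JSON."""

    def __init__(self, entries: Iterable[KnowledgeBaseEntry]):
        self.entries: tuple[KnowledgeBaseEntry, ...] = tuple(entries)
        self._by_gene: dict[str, list[KnowledgeBaseEntry]] = {}
        for e in self.entries:
            self._by_gene.setdefault(e.gene, []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def for_gene(self, gene: str) -> Sequence[KnowledgeBaseEntry]:
        return self._by_gene.get(gene, ())

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "KnowledgeBase":
        entries = []
        for rec in records:
            entries.append(
                KnowledgeBaseEntry(
                    entry_id=str(rec["entry_id"]),
                    gene=str(rec["gene"]),
                    alt_pattern=str(rec.get("alt_pattern", ANY)),
                    context=str(rec.get("context", ANY)),
                    evidence=str(rec.get("evidence", "BIOLOGICAL_ONLY")),
                    germline_risk=str(rec.get("germline_risk", "NONE")),
                    germline_therapeutic=_as_bool(rec.get("germline_therapeutic", False)),
                )
            )
        return cls(entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "KnowledgeBase":
        path = Path(path)
        if path.suffix == ".json":
            return cls.from_records(json.loads(path.read_text()))
        frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        records = []
        for rec in frame.to_dict(orient="records"):
            rec = {k: v for k, v in rec.items() if v != ""}
            records.append(rec)
        return cls.from_records(records)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        rows = [
            {
                "entry_id": e.entry_id,
                "gene": e.gene,
                "alt_pattern": e.alt_pattern,
                "context": e.context,
                "evidence": e.evidence,
                "germline_risk": e.germline_risk,
                "germline_therapeutic": e.germline_therapeutic,
            }
            for e in self.entries
        ]
        if path.suffix == ".json":
            path.write_text(json.dumps(rows, indent=1))
        else:
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes")


#: evidence level -> (tier, subcategory) when the entry's context matches
_EVIDENCE_TIER = {
    "FDA_APPROVED_BENEFIT": (1, "S"),
    "FDA_APPROVED_RESISTANCE": (1, "R"),
    "INVESTIGATIONAL_OR_OFF_LABEL": (2, "S"),
    "PRECLINICAL_RESISTANCE": (2, "R"),
    "BIOLOGICAL_ONLY": (3, "S"),
}


def assign_tier(
    alt: Alteration,
    kb: KnowledgeBase,
    diagnosis_changed: bool = False,
) -> TierAssignment:
    """Assign one validated alteration its tier and subcategory.

    All matching rules are evaluated and the highest-priority one wins:
    tier 1 beats 2 beats 3; within a tier the subcategory order G < D < S < R
    breaks ties, then the knowledge-base entry id. An FDA-approved therapy
    matched outside its approved indication yields a tier-2 (off-label) call
    rather than tier 1. An alteration matching nothing falls through to
    tier 3 S with empty rationale.
    """
    candidates: list[TierAssignment] = []

    if alt.origin == "germline" and alt.pathogenicity in ("pathogenic", "likely_pathogenic"):
        for entry in kb.for_gene(alt.gene):
            if entry.germline_risk in _CANCER_RISK:
                candidates.append(
                    TierAssignment(1, "G", entry.germline_therapeutic, entry)
                )

    if diagnosis_changed and alt.alt_class == "diagnosis_marker":
        candidates.append(TierAssignment(1, "D"))

    if alt.origin == "somatic":
        for entry in kb.for_gene(alt.gene):
            if not entry.matches_class(alt.alt_class):
                continue
            tier, subcat = _EVIDENCE_TIER[entry.evidence]
            if not entry.matches_context(alt.cancer_type):
                if entry.evidence in ("FDA_APPROVED_BENEFIT", "FDA_APPROVED_RESISTANCE"):
                    # approved drug, other indication: off-label rationale only
                    tier = 2
                else:
                    continue
            candidates.append(TierAssignment(tier, subcat, False, entry))

    if not candidates:
        return TierAssignment(3, "S", False, None)
    return min(candidates, key=TierAssignment.sort_key)


@dataclass(frozen=True)
class ActionabilitySummary:
    """Cohort-level actionability counts (one vote per patient)."""

    n_patients: int
    n_actionable: int  # patients with >= 1 tier-1 or tier-2 assignment
    n_tier1: int
    n_tier2_somatic: int  # patients with >= 1 tier-2 S somatic rationale
    actionable_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "actionable_fraction", self.n_actionable / self.n_patients
        )


def summarize_actionability(
    assignments: Mapping[str, Sequence[TierAssignment]],
) -> ActionabilitySummary:
    """Per-patient actionability flags from tier assignments.

    A patient is actionable when any of their alterations is tier 1 or 2;
    duplicate records cannot inflate the count because flags are per patient.
    """
    if not assignments:
        raise ValidationError("empty cohort: no tier assignments to summarize")
    n_actionable = n_tier1 = n_tier2s = 0
    for _, calls in assignments.items():
        calls = list(calls)
        if any(c.actionable for c in calls):
            n_actionable += 1
        if any(c.tier == 1 for c in calls):
            n_tier1 += 1
        if any(c.tier == 2 and c.subcategory == "S" for c in calls):
            n_tier2s += 1
    return ActionabilitySummary(
        n_patients=len(assignments),
        n_actionable=n_actionable,
        n_tier1=n_tier1,
        n_tier2_somatic=n_tier2s,
    )
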