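"""Pathogenic germline variant (PGV) categorization and second-hit calling.

PGVs found by tumor/normal sequencing are grouped into four predisposition
categories — highly penetrant syndrome, moderately penetrant syndrome,
autosomal-recessive condition with cancer risk, autosomal-recessive condition
without known cancer risk — from a gene panel table. Genes whose loss creates
a therapeutic vulnerability are flagged as therapeutic targets: defects in
double-strand-break repair (BRCA1, BRCA2, ATM, PALB2, BRIP1; PARP-inhibitor
rationale) and in DNA mismatch repair (MLH1, MSH2, PMS2; immune-checkpoint
rationale).

A somatic "second hit" follows the classical two-hit model: the tumor carries
an additional somatic event — mutation, homozygous deletion, or loss of
heterozygosity — in the same gene as the germline variant, inactivating the
remaining allele. Loss of heterozygosity is taken as an explicit event class
in the somatic table rather than recomputed from allele fractions, which
keeps the call auditable from tabular inputs.

The bundled panel covers the genes named in the source cohort's main figures
and is a plain TSV so users can extend it to their own panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .tiering import Alteration, ValidationError
from .utils import percent

DSB_REPAIR_GENES = frozenset({"BRCA1", "BRCA2", "ATM", "PALB2", "BRIP1"})
MMR_GENES = frozenset({"MLH1", "MSH2", "PMS2"})

PGV_CATEGORIES = (
    "HIGH_PENETRANT",
    "MODERATE_PENETRANT",
    "AR_CANCER_RISK",
    "AR_NONCANCER",
)

#: somatic event classes that count as a second hit in the same gene
SECOND_HIT_CLASSES = frozenset({"mutation", "homozygous_deletion", "loh"})


@dataclass(frozen=True)
class PGVRecord:
    patient_id: str
    gene: str
    pathogenicity: str  # pathogenic | likely_pathogenic
    category: str
    known_before_enrollment: bool = False
    therapeutic_target: bool = False
    second_hit: bool | None = None  # None = undetermined

    def __post_init__(self) -> None:
        if self.pathogenicity not in ("pathogenic", "likely_pathogenic"):
            raise ValidationError(
                f"PGV pathogenicity must be pathogenic/likely_pathogenic, got {self.pathogenicity!r}"
            )
        if self.category not in PGV_CATEGORIES:
            raise ValidationError(f"unknown PGV category {self.category!r}")


class GenePanel:
    """gene -> (predisposition category, therapeutic-target flag).

    The therapeutic flag is forced true for DSB-repair and MMR genes
    regardless of what the table says, since it is defined by membership in
    those sets.
    """

    def __init__(self, table: Mapping[str, str]):
        self._category = dict(table)
        for gene, cat in self._category.items():
            if cat not in PGV_CATEGORIES:
                raise ValidationError(f"panel gene {gene}: unknown category {cat!r}")

    def __contains__(self, gene: str) -> bool:
        return gene in self._category

    def genes(self) -> list[str]:
        return sorted(self._category)

    def category(self, gene: str) -> str:
        return self._category[gene]

    def therapeutic_target(self, gene: str) -> bool:
        return gene in DSB_REPAIR_GENES or gene in MMR_GENES

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenePanel":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(frame["gene"], frame["category"])))

    @classmethod
    def default(cls) -> "GenePanel":
        with resources.as_file(
            resources.files("oncoprofile.data").joinpath("gene_panel.tsv")
        ) as path:
            return cls.from_tsv(path)


def categorize_pgv(
    gene: str, panel: GenePanel, on_unknown: str = "raise"
) -> tuple[str | None, bool]:
    """Look up a germline gene's predisposition category and therapeutic flag.

    ``on_unknown`` controls genes absent from the panel: "raise" rejects them,
    "none" returns (None, False) so callers can warn and continue.
    """
    if gene not in panel:
        if on_unknown == "none":
            return None, False
        raise ValidationError(f"gene {gene!r} not present in the panel")
    return panel.category(gene), panel.therapeutic_target(gene)


def detect_second_hit(pgv: PGVRecord, somatic_events: Sequence[Alteration]) -> bool:
    """True iff the tumor carries an inactivating somatic event in the PGV's gene.

    Qualifying classes: mutation, homozygous deletion, loss of heterozygosity.
    Order of the somatic list is irrelevant.
    """
    for event in somatic_events:
        if event.patient_id != pgv.patient_id:
            raise ValidationError(
                f"somatic event for {event.patient_id} passed with PGV of {pgv.patient_id}"
            )
    return any(
        e.gene == pgv.gene and e.origin == "somatic" and e.alt_class in SECOND_HIT_CLASSES
        for e in somatic_events
    )


def annotate_second_hits(
    pgvs: Iterable[PGVRecord], somatic: Iterable[Alteration]
) -> list[PGVRecord]:
    """Return copies of the PGV records with second_hit filled in per patient."""
    by_patient: dict[str, list[Alteration]] = {}
    for event in somatic:
        if event.origin == "somatic":
            by_patient.setdefault(event.patient_id, []).append(event)
    out = []
    for pgv in pgvs:
        hit = detect_second_hit(pgv, by_patient.get(pgv.patient_id, ()))
        out.append(
            PGVRecord(
                patient_id=pgv.patient_id,
                gene=pgv.gene,
                pathogenicity=pgv.pathogenicity,
                category=pgv.category,
                known_before_enrollment=pgv.known_before_enrollment,
                therapeutic_target=pgv.therapeutic_target,
                second_hit=hit,
            )
        )
    return out


@dataclass(frozen=True)
class GermlineSummary:
    n_pgvs: int
    n_patients: int
    cohort_size: int
    pct_of_cohort: float
    category_counts: Mapping[str, int]
    pct_penetrant: float  # high + moderate syndromes among all PGVs
    n_second_hit: int
    pct_second_hit: float
    n_therapeutic: int
    n_therapeutic_second_hit: int
    pct_therapeutic_second_hit: float
    n_unknown_before: int
    pct_unknown_before: float


def summarize_pgvs(records: Sequence[PGVRecord], cohort_size: int) -> GermlineSummary:
    """Cohort germline summary: counts per category, second-hit and novelty rates.

    An empty record set yields an all-zero summary (a cohort with no PGVs is a
    valid result, not an error). Percentages are rounded half-up to one
    decimal, matching how cohort tables are printed.
    """
    records = list(records)
    patients = {r.patient_id for r in records}
    if cohort_size < len(patients):
        raise ValidationError("cohort_size smaller than number of unique PGV patients")
    cat_counts = {c: 0 for c in PGV_CATEGORIES}
    for r in records:
        cat_counts[r.category] += 1
    n = len(records)
    n_second = sum(1 for r in records if r.second_hit)
    n_thera = sum(1 for r in records if r.therapeutic_target)
    n_thera_second = sum(1 for r in records if r.therapeutic_target and r.second_hit)
    n_unknown = sum(1 for r in records if not r.known_before_enrollment)
    n_penetrant = cat_counts["HIGH_PENETRANT"] + cat_counts["MODERATE_PENETRANT"]
    pct = lambda num, den: percent(num, den) if den else 0.0  # noqa: E731
    return GermlineSummary(
        n_pgvs=n,
        n_patients=len(patients),
        cohort_size=cohort_size,
        pct_of_cohort=pct(len(patients), cohort_size),
        category_counts=cat_counts,
        pct_penetrant=pct(n_penetrant, n),
        n_second_hit=n_second,
        pct_second_hit=pct(n_second, n),
        n_therapeutic=n_thera,
        n_therapeutic_second_hit=n_thera_second,
        pct_therapeutic_second_hit=pct(n_thera_second, n_thera),
        n_unknown_before=n_unknown,
        pct_unknown_before=pct(n_unknown, n),
    )
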