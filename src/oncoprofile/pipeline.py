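"""End-to-end reproducible run: simulate -> classify -> tier -> germline -> outcomes.

One seed drives everything; per-stage generators are derived substreams of a
single root SeedSequence, so a run is byte-stable given its config. The run
emits a per-patient report (TSV + JSON), a cohort summary, and a manifest
recording the config hash.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import (
    classify_cohort,
    contaminate_profile,
    normalize_profile,
    train_ensemble,
    uniform_alpha,
)
from .germline import GenePanel, annotate_second_hits, summarize_pgvs
from .outcomes import CohortCounts, classify_course, cohort_rates
from .synthetic import (
    DurationMixture,
    generate_clinical_table,
    generate_expression_corpus,
    split_corpus,
    synthetic_knowledge_base,
)
from .tiering import KnowledgeBase, ValidationError, assign_tier, summarize_actionability
from .utils import derive_seed


@dataclass
class RunConfig:
    """Configuration for one reproducible pipeline run."""

    seed: int
    outdir: str = "oncoprofile_run"
    # expression corpus
    n_tissues: int = 5
    n_sites: int = 3
    n_genes: int = 200
    n_per_tissue: int = 40
    noise_sd: float = 0.5
    test_per_tissue: int = 10
    test_alpha: float = 0.2
    # tissue-of-origin settings
    threshold: float = 0.6
    alpha_low: float = 0.0
    alpha_high: float = 0.5
    hyperparams: dict = field(default_factory=dict)
    # clinical cohort
    n_patients: int = 1015
    actionable_fraction: float = 0.805
    pgv_fraction: float = 0.158
    second_hit_fraction: float = 0.408
    # resources
    kb_path: str | None = None
    panel_path: str | None = None
    censor_date: str = "2020-04-30"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValidationError("config must set a seed")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("kb_path", "panel_path"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ValidationError(f"{name} does not resolve: {value}")
        dt.date.fromisoformat(self.censor_date)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage on a synthetic cohort and write the run report.

    Returns the report dict; files written under ``config.outdir``:
    ``per_patient.tsv``, ``report.json``, ``manifest.json``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    corpus_seed, clinical_seed, ensemble_seed = (derive_seed(s) for s in root.spawn(3))
    kb = KnowledgeBase.from_file(config.kb_path) if config.kb_path else synthetic_knowledge_base()
    panel = GenePanel.from_tsv(config.panel_path) if config.panel_path else GenePanel.default()
    censor = dt.date.fromisoformat(config.censor_date)

    # 1. tissue-of-origin on a held-out contaminated CUP cohort
    corpus = generate_expression_corpus(
        config.n_tissues,
        config.n_sites,
        config.n_genes,
        config.n_per_tissue,
        config.noise_sd,
        corpus_seed,
    )
    train, test = split_corpus(corpus, config.test_per_tissue)
    model = train_ensemble(
        train,
        alpha_sampler=uniform_alpha(config.alpha_low, config.alpha_high),
        hyperparams=config.hyperparams,
        threshold=config.threshold,
        seed=ensemble_seed,
    )
    cases = []
    gene_ids = tuple(test.expression.index)
    for sample in test.expression.columns:
        site = test.site_labels[sample]
        profile = normalize_profile(test.expression[sample].to_numpy(), gene_ids, site)
        normal = normalize_profile(test.normal_panel[site].to_numpy(), gene_ids, site)
        cases.append(
            (contaminate_profile(profile, normal, config.test_alpha), "CUP")
        )
    cup_report = classify_cohort(model, cases)
    cup_report["true_tissue"] = list(test.tissue_labels)
    cup_report["sample"] = list(test.expression.columns)
    classified = cup_report[cup_report["predicted"] != "UNCLASSIFIED"]
    too_accuracy = (
        float((classified["predicted"] == classified["true_tissue"]).mean())
        if len(classified)
        else 0.0
    )

    # 2. clinical cohort: tiering, germline, outcomes
    clinical = generate_clinical_table(
        config.n_patients,
        config.actionable_fraction,
        config.pgv_fraction,
        config.second_hit_fraction,
        DurationMixture(),
        clinical_seed,
        panel=panel,
    )
    assignments = {pid: [] for pid in clinical.patients}
    for alt in clinical.alterations:
        assignments[alt.patient_id].append(assign_tier(alt, kb))
    actionability = summarize_actionability(assignments)

    pgvs = annotate_second_hits(clinical.pgvs, clinical.alterations)
    germline = summarize_pgvs(pgvs, cohort_size=config.n_patients)

    sdt_courses = [c for c in clinical.courses if c.sdt]
    benefit_patients, exceptional_patients = set(), set()
    course_rows = []
    for course in sdt_courses:
        flags = classify_course(course, censor)
        if flags["benefit"]:
            benefit_patients.add(course.patient_id)
        if flags["exceptional"]:
            exceptional_patients.add(course.patient_id)
        course_rows.append({"patient_id": course.patient_id, **flags})

    counts = CohortCounts(
        n_cohort=config.n_patients,
        n_actionable=actionability.n_actionable,
        n_tier2_somatic=actionability.n_tier2_somatic,
        n_sdt_patients=len({c.patient_id for c in sdt_courses}),
        n_benefit=len(benefit_patients),
        n_exceptional=len(exceptional_patients),
        n_pgv_patients=germline.n_patients,
        n_pgv_total=germline.n_pgvs,
        n_pgv_unknown_before=germline.n_unknown_before,
        n_pgv_penetrant=germline.category_counts["HIGH_PENETRANT"]
        + germline.category_counts["MODERATE_PENETRANT"],
        n_second_hit=germline.n_second_hit,
        n_pgv_therapeutic=germline.n_therapeutic,
        n_pgv_therapeutic_second_hit=germline.n_therapeutic_second_hit,
        n_cup=len(cases),
        n_cup_reclassified=int(cup_report["reclassified"].sum()),
        n_cup_sdt_instances=0,
        n_cup_benefit_instances=0,
    )
    summary = cohort_rates(counts)

    # 3. per-patient report
    per_patient = clinical.truth.copy()
    tier_best = {
        pid: min((a.tier for a in calls), default=0) for pid, calls in assignments.items()
    }
    per_patient["best_tier"] = pd.Series(tier_best)
    per_patient["actionable_called"] = per_patient["best_tier"].isin([1, 2])
    hit_by_patient = {p.patient_id: bool(p.second_hit) for p in pgvs}
    per_patient["second_hit_called"] = [
        hit_by_patient.get(pid, False) for pid in per_patient.index
    ]
    per_patient["benefit"] = per_patient.index.isin(benefit_patients)
    per_patient["exceptional"] = per_patient.index.isin(exceptional_patients)
    per_patient.to_csv(outdir / "per_patient.tsv", sep="\t")
    cup_report.to_csv(outdir / "cup_cases.tsv", sep="\t", index=False)

    report = {
        "tissue_of_origin": {
            "n_cases": len(cases),
            "n_reclassified": int(cup_report["reclassified"].sum()),
            "reclassified_fraction": cup_report.attrs["reclassified_fraction"],
            "accuracy_among_classified": too_accuracy,
        },
        "actionability": dataclasses.asdict(actionability),
        "germline": {
            **{
                k: v
                for k, v in dataclasses.asdict(germline).items()
                if k != "category_counts"
            },
            "category_counts": dict(germline.category_counts),
        },
        "outcomes": {
            "n_sdt_courses": len(sdt_courses),
            "n_benefit_patients": len(benefit_patients),
            "n_exceptional_patients": len(exceptional_patients),
        },
        "cohort_summary": summary.as_dict(),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    manifest = {
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "version": __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return report
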