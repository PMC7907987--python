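"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

Two generators:

``generate_expression_corpus`` builds a labeled gene x sample expression
matrix. Each tissue class has a marker-gene block (default 10 genes) whose
log-expression is shifted upward by a fixed effect (default 2.0 log units)
over a shared baseline; per-sample log-values are Gaussian around the tissue
mean and exponentiated, so the linear-scale matrix is log-normal and strictly
nonnegative. A per-site normal panel — the mean of dedicated "normal" draws
from a site-specific profile without tumor markers — supplies the
contamination signal for classifier training.

``generate_clinical_table`` builds per-patient alteration tables with planted
actionability tiers, pathogenic germline variants with planted somatic second
hits, and sequencing-directed therapy courses with durations drawn from a
responder/non-responder mixture. Planted truths are recorded separately from
the observable tables so recovery can be scored.

The generators emulate class structure, admixture, and planted rates only;
they make no attempt to mimic real compendium expression distributions,
batch effects, or true gene identifiers.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .germline import GenePanel, PGVRecord
from .outcomes import DAYS_PER_MONTH, TherapyCourse
from .tiering import Alteration, KnowledgeBase, KnowledgeBaseEntry, ValidationError

MARKER_BLOCK_SIZE = 10
MARKER_EFFECT = 2.0
SITE_OFFSET_SD = 0.75
N_NORMAL_DRAWS = 20


@dataclass(frozen=True)
class TissueSpec:
    """One tissue class: marker-gene block and log-scale mean profile."""

    label: str
    marker_genes: tuple[int, ...]
    baseline_mean: np.ndarray  # per-gene log-scale location, markers included
    marker_effect: float

    def __post_init__(self) -> None:
        if self.marker_effect <= 0:
            raise ValidationError("marker_effect must be positive")


@dataclass
class SyntheticCorpus:
    """Labeled expression matrix plus the per-site normal panel."""

    expression: pd.DataFrame  # genes x samples, linear nonnegative scale
    tissue_labels: pd.Series  # sample -> tissue class
    site_labels: pd.Series  # sample -> biopsy site
    normal_panel: pd.DataFrame  # genes x sites, linear scale
    seed: int
    tissue_specs: tuple[TissueSpec, ...] = ()

    def __post_init__(self) -> None:
        samples = list(self.expression.columns)
        if list(self.tissue_labels.index) != samples or list(self.site_labels.index) != samples:
            raise ValidationError("labels must cover exactly the expression samples")
        if (self.expression.to_numpy() < 0).any():
            raise ValidationError("expression values must be nonnegative")
        missing = set(self.site_labels) - set(self.normal_panel.columns)
        if missing:
            raise ValidationError(f"normal panel missing sites: {sorted(missing)}")


def generate_expression_corpus(
    n_tissues: int,
    n_sites: int,
    n_genes: int,
    n_per_tissue: int,
    noise_sd: float,
    seed: int,
    marker_block: int = MARKER_BLOCK_SIZE,
    marker_effect: float = MARKER_EFFECT,
) -> SyntheticCorpus:
    """Simulate a labeled tissue-expression corpus.

    Within a tissue, sample log-expression is Gaussian(tissue mean, noise_sd)
    — with ``noise_sd=0`` all samples of a tissue are identical. Samples are
    assigned to biopsy sites round-robin so each tissue covers every site
    (requires ``n_per_tissue >= n_sites``). Deterministic given ``seed``.
    """
    if min(n_tissues, n_sites, n_genes, n_per_tissue) < 1:
        raise ValidationError("all counts must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    if n_genes < n_tissues * marker_block:
        raise ValidationError(
            f"need at least {n_tissues * marker_block} genes for {n_tissues} marker blocks"
        )
    if n_per_tissue < n_sites:
        raise ValidationError("need n_per_tissue >= n_sites to cover every site per tissue")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sites = [f"site_{j + 1}" for j in range(n_sites)]
    baseline = rng.normal(1.0, 0.5, n_genes)

    specs = []
    for t in range(n_tissues):
        markers = tuple(range(t * marker_block, (t + 1) * marker_block))
        mean = baseline.copy()
        mean[list(markers)] += marker_effect
        specs.append(
            TissueSpec(f"tissue_{t + 1:02d}", markers, mean, marker_effect)
        )

    # site-specific normal profiles: baseline plus a per-gene site offset,
    # no tumor marker blocks
    site_offsets = {s: rng.normal(0.0, SITE_OFFSET_SD, n_genes) for s in sites}

    columns, tissue_lab, site_lab = [], [], []
    data = np.empty((n_genes, n_tissues * n_per_tissue))
    k = 0
    for spec in specs:
        for j in range(n_per_tissue):
            noise = rng.normal(0.0, noise_sd, n_genes) if noise_sd > 0 else 0.0
            data[:, k] = np.exp(spec.baseline_mean + noise)
            columns.append(f"S{k + 1:04d}")
            tissue_lab.append(spec.label)
            site_lab.append(sites[j % n_sites])
            k += 1

    panel = {}
    for s in sites:
        site_mean = baseline + site_offsets[s]
        draws = np.exp(
            site_mean[:, None]
            + (rng.normal(0.0, noise_sd, (n_genes, N_NORMAL_DRAWS)) if noise_sd > 0 else 0.0)
        )
        panel[s] = draws.mean(axis=1)

    gene_index = pd.Index(gene_ids, name="gene")
    sample_index = pd.Index(columns, name="sample")
    return SyntheticCorpus(
        expression=pd.DataFrame(data, index=gene_index, columns=sample_index),
        tissue_labels=pd.Series(tissue_lab, index=sample_index, name="tissue"),
        site_labels=pd.Series(site_lab, index=sample_index, name="site"),
        normal_panel=pd.DataFrame(panel, index=gene_index),
        seed=seed,
        tissue_specs=tuple(specs),
    )


def split_corpus(
    corpus: SyntheticCorpus, test_per_tissue: int
) -> tuple[SyntheticCorpus, SyntheticCorpus]:
    """Hold out the last ``test_per_tissue`` samples of each tissue class."""
    test_samples: list[str] = []
    for tissue in corpus.tissue_labels.unique():
        members = corpus.tissue_labels.index[corpus.tissue_labels == tissue]
        if len(members) <= test_per_tissue:
            raise ValidationError("not enough samples per tissue to hold out a test set")
        test_samples.extend(members[-test_per_tissue:])
    train_samples = [s for s in corpus.expression.columns if s not in set(test_samples)]

    def _take(samples: list[str]) -> SyntheticCorpus:
        return SyntheticCorpus(
            expression=corpus.expression[samples],
            tissue_labels=corpus.tissue_labels[samples],
            site_labels=corpus.site_labels[samples],
            normal_panel=corpus.normal_panel,
            seed=corpus.seed,
            tissue_specs=corpus.tissue_specs,
        )

    return _take(train_samples), _take(test_samples)


# --- clinical table -----------------------------------------------------

#: genes used for planted somatic alterations, split by intended tier
TIER1_GENES = ("ERBB2", "EGFR", "BRAF", "ALK", "KIT")
TIER2_GENES = ("CDK4", "FGFR2", "MET", "PIK3CA", "PTCH1")
TIER3_GENES = ("TP53", "ARID1A", "KMT2D", "SPOP", "CTNNB1")

CANCER_TYPES = ("breast", "prostate", "sarcoma", "cholangiocarcinoma", "CUP")

#: fraction of actionable patients planted as tier 1 rather than tier 2
TIER1_SHARE = 0.3
#: probability of an extra biological-only (tier 3) event per patient
TIER3_RATE = 0.5
#: fraction of PGVs already known before enrollment
KNOWN_BEFORE_RATE = 0.083
#: fraction of actionable patients starting sequencing-directed therapy
SDT_RATE = 0.162


def synthetic_knowledge_base() -> KnowledgeBase:
    """A frozen toy therapy knowledge base matched to the planted genes."""
    entries = []
    for i, gene in enumerate(TIER1_GENES):
        entries.append(
            KnowledgeBaseEntry(f"KB1{i:02d}", gene, "ANY", "ANY", "FDA_APPROVED_BENEFIT")
        )
    for i, gene in enumerate(TIER2_GENES):
        entries.append(
            KnowledgeBaseEntry(
                f"KB2{i:02d}", gene, "ANY", "ANY", "INVESTIGATIONAL_OR_OFF_LABEL"
            )
        )
    for i, gene in enumerate(TIER3_GENES):
        entries.append(
            KnowledgeBaseEntry(f"KB3{i:02d}", gene, "ANY", "ANY", "BIOLOGICAL_ONLY")
        )
    panel = GenePanel.default()
    for i, gene in enumerate(panel.genes()):
        if panel.category(gene) == "AR_NONCANCER":
            continue
        entries.append(
            KnowledgeBaseEntry(
                f"KBG{i:02d}",
                gene,
                "mutation",
                "ANY",
                "BIOLOGICAL_ONLY",
                germline_risk=panel.category(gene),
                germline_therapeutic=panel.therapeutic_target(gene),
            )
        )
    return KnowledgeBase(entries)


@dataclass(frozen=True)
class DurationMixture:
    """SDT duration model: short exponential non-responders plus long uniform
    responders, in months."""

    p_responder: float = 0.371
    nonresponder_scale: float = 2.0
    responder_range: tuple[float, float] = (6.0, 40.0)

    def draw(self, rng: np.random.Generator) -> tuple[float, bool]:
        responder = bool(rng.random() < self.p_responder)
        if responder:
            months = float(rng.uniform(*self.responder_range))
        else:
            months = float(rng.exponential(self.nonresponder_scale))
        return months, responder


@dataclass
class SyntheticClinicalTable:
    """Observable clinical tables plus the planted ground truth."""

    patients: list[str]
    alterations: list[Alteration]
    pgvs: list[PGVRecord]
    courses: list[TherapyCourse]
    truth: pd.DataFrame  # one row per patient: planted flags
    seed: int

    def __post_init__(self) -> None:
        known = set(self.patients)
        for alt in self.alterations:
            if alt.patient_id not in known:
                raise ValidationError(f"alteration references unknown patient {alt.patient_id}")
        for pgv in self.pgvs:
            if pgv.patient_id not in known:
                raise ValidationError(f"PGV references unknown patient {pgv.patient_id}")
        for course in self.courses:
            if course.patient_id not in known:
                raise ValidationError(f"course references unknown patient {course.patient_id}")


def _planted_subset(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask with randomized-rounded count ``n * fraction``, placed at random."""
    if n == 0:
        return np.zeros(0, dtype=bool)
    base, remainder = divmod(n * fraction, 1.0)
    count = int(base) + int(rng.random() < remainder)
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:count]] = True
    return mask


def generate_clinical_table(
    n_patients: int,
    actionable_fraction: float,
    pgv_fraction: float,
    second_hit_fraction: float,
    benefit_duration_dist: DurationMixture | None = None,
    seed: int = 0,
    panel: GenePanel | None = None,
) -> SyntheticClinicalTable:
    """Simulate per-patient alteration, germline and therapy-course tables.

    Planted flags use randomized rounding: exactly ``floor(n * fraction)``
    patients (plus one more with probability equal to the fractional part)
    are drawn at random, so the expected prevalence equals the requested
    fraction and the realized prevalence is within one patient of it for
    every seed. Actionable patients are planted as tier 1 or tier 2 against
    the bundled synthetic knowledge base; PGV carriers get a second hit at
    ``second_hit_fraction``; actionable patients start sequencing-directed
    therapy at a fixed uptake rate, with durations from the
    responder/non-responder mixture. Deterministic given ``seed``.
    """
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    for name, frac in (
        ("actionable_fraction", actionable_fraction),
        ("pgv_fraction", pgv_fraction),
        ("second_hit_fraction", second_hit_fraction),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1]")
    mixture = benefit_duration_dist or DurationMixture()
    panel = panel or GenePanel.default()
    rng = np.random.default_rng(seed)
    germline_genes = [g for g in panel.genes() if panel.category(g) != "AR_NONCANCER"]

    patients = [f"P{i + 1:05d}" for i in range(n_patients)]
    alterations: list[Alteration] = []
    pgvs: list[PGVRecord] = []
    courses: list[TherapyCourse] = []
    truth_rows = []
    epoch = dt.date(2018, 1, 1)

    actionable_flags = _planted_subset(n_patients, actionable_fraction, rng)
    pgv_flags = _planted_subset(n_patients, pgv_fraction, rng)
    hit_flags = np.zeros(n_patients, dtype=bool)
    carriers = np.flatnonzero(pgv_flags)
    hit_flags[carriers[_planted_subset(len(carriers), second_hit_fraction, rng)]] = True

    for i, pid in enumerate(patients):
        cancer_type = str(rng.choice(CANCER_TYPES))
        actionable = bool(actionable_flags[i])
        planted_tier = 0
        if actionable:
            if rng.random() < TIER1_SHARE:
                planted_tier = 1
                gene = str(rng.choice(TIER1_GENES))
            else:
                planted_tier = 2
                gene = str(rng.choice(TIER2_GENES))
            alt_class = str(rng.choice(("mutation", "amplification", "fusion")))
            alterations.append(
                Alteration(pid, gene, alt_class, "somatic", cancer_type=cancer_type)
            )
        if rng.random() < TIER3_RATE:
            alterations.append(
                Alteration(
                    pid,
                    str(rng.choice(TIER3_GENES)),
                    "mutation",
                    "somatic",
                    cancer_type=cancer_type,
                )
            )

        has_pgv = bool(pgv_flags[i])
        planted_hit = False
        if has_pgv:
            gene = str(rng.choice(germline_genes))
            pathogenicity = str(rng.choice(("pathogenic", "likely_pathogenic")))
            planted_hit = bool(hit_flags[i])
            pgvs.append(
                PGVRecord(
                    patient_id=pid,
                    gene=gene,
                    pathogenicity=pathogenicity,
                    category=panel.category(gene),
                    known_before_enrollment=bool(rng.random() < KNOWN_BEFORE_RATE),
                    therapeutic_target=panel.therapeutic_target(gene),
                    second_hit=None,  # observable call made downstream
                )
            )
            alterations.append(
                Alteration(pid, gene, "mutation", "germline", pathogenicity, cancer_type)
            )
            if planted_hit:
                hit_class = str(rng.choice(("mutation", "homozygous_deletion", "loh")))
                alterations.append(
                    Alteration(pid, gene, hit_class, "somatic", cancer_type=cancer_type)
                )

        sdt = actionable and bool(rng.random() < SDT_RATE)
        planted_months = np.nan
        planted_responder = False
        if sdt:
            months, planted_responder = mixture.draw(rng)
            planted_months = months
            start = epoch + dt.timedelta(days=int(rng.integers(0, 365)))
            stop = start + dt.timedelta(days=int(round(months * DAYS_PER_MONTH)))
            if planted_responder:
                response = str(rng.choice(("CR", "PR", "SD"), p=(0.15, 0.55, 0.30)))
            else:
                response = str(rng.choice(("PD", "SD"), p=(0.8, 0.2)))
            courses.append(
                TherapyCourse(
                    patient_id=pid,
                    therapy=f"drug_{rng.integers(1, 30):02d}",
                    sdt=True,
                    start=start,
                    stop=stop,
                    setting=str(rng.choice(SETTING_CHOICES, p=SETTING_PROBS)),
                    best_response=response,
                )
            )

        truth_rows.append(
            {
                "patient_id": pid,
                "cancer_type": cancer_type,
                "actionable": actionable,
                "planted_tier": planted_tier,
                "has_pgv": has_pgv,
                "planted_second_hit": planted_hit,
                "sdt": sdt,
                "planted_duration_months": planted_months,
                "planted_responder": planted_responder,
            }
        )

    return SyntheticClinicalTable(
        patients=patients,
        alterations=alterations,
        pgvs=pgvs,
        courses=courses,
        truth=pd.DataFrame(truth_rows).set_index("patient_id"),
        seed=seed,
    )


SETTING_CHOICES = ("trial", "off_label", "on_label")
SETTING_PROBS = (0.56, 0.33, 0.11)  # trial-heavy mix typical of sequencing programs


# --- on-disk form -------------------------------------------------------


def write_corpus(corpus: SyntheticCorpus, outdir: str | Path, params: dict | None = None) -> None:
    """Write a corpus as plain TSVs plus a manifest recording seed and params."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corpus.expression.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene")
    labels = pd.DataFrame(
        {"tissue": corpus.tissue_labels, "site": corpus.site_labels}
    )
    labels.to_csv(outdir / "labels.tsv", sep="\t", index_label="sample")
    corpus.normal_panel.to_csv(outdir / "normal_panel.tsv", sep="\t", index_label="gene")
    manifest = {"seed": corpus.seed, "params": params or {}}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_corpus(indir: str | Path) -> SyntheticCorpus:
    indir = Path(indir)
    expression = pd.read_csv(indir / "expression.tsv", sep="\t", index_col="gene")
    expression.columns.name = "sample"
    labels = pd.read_csv(indir / "labels.tsv", sep="\t", index_col="sample")
    panel = pd.read_csv(indir / "normal_panel.tsv", sep="\t", index_col="gene")
    manifest = json.loads((indir / "manifest.json").read_text())
    return SyntheticCorpus(
        expression=expression,
        tissue_labels=labels["tissue"],
        site_labels=labels["site"],
        normal_panel=panel,
        seed=int(manifest["seed"]),
    )


def write_clinical_table(
    table: SyntheticClinicalTable, outdir: str | Path, params: dict | None = None
) -> None:
    """Write alteration/PGV/course tables as MAF-like TSVs plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "patient_id": a.patient_id,
                "gene": a.gene,
                "alt_class": a.alt_class,
                "origin": a.origin,
                "pathogenicity": a.pathogenicity or "",
                "cancer_type": a.cancer_type,
            }
            for a in table.alterations
        ]
    ).to_csv(outdir / "alterations.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "gene": p.gene,
                "pathogenicity": p.pathogenicity,
                "category": p.category,
                "known_before_enrollment": p.known_before_enrollment,
                "therapeutic_target": p.therapeutic_target,
            }
            for p in table.pgvs
        ]
    ).to_csv(outdir / "pgvs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "therapy": c.therapy,
                "sdt": c.sdt,
                "setting": c.setting or "",
                "start": c.start.isoformat(),
                "stop": c.stop.isoformat() if c.stop else "",
                "best_response": c.best_response,
            }
            for c in table.courses
        ]
    ).to_csv(outdir / "courses.tsv", sep="\t", index=False)
    table.truth.to_csv(outdir / "planted_truth.tsv", sep="\t")
    manifest = {"seed": table.seed, "params": params or {}}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
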