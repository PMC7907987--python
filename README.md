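# oncoprofile

Analytics for integrative (DNA + RNA) tumor profiling cohorts, aimed at
computational oncologists who need the downstream half of a precision-oncology
program as reusable, tested code: tissue-of-origin estimation for carcinomas of
unknown primary (CUP), clinical actionability tiering of somatic and germline
alterations, pathogenic-germline-variant (PGV) second-hit analysis, and
duration-based clinical-benefit statistics. A seeded synthetic-cohort generator
stands in for controlled-access patient data, so every stage runs end to end
out of the box.

## The methods

**Contamination-aware tissue-of-origin ensemble.** A metastatic biopsy mixes
tumor transcripts with normal transcripts from the biopsy site. Writing a
profile's linear-scale expression as

    x_obs = (1 − α) · x_tumor + α · x_normal,   α ∈ [0, 1],

the classifier is trained on labeled tumor profiles deliberately admixed this
way under three schemes — no contamination, the sample's own biopsy-site normal
profile, and the unweighted mean of all site normal profiles — crossed with two
learners, a ν-support-vector machine and an L1-penalized (lasso) multinomial
logistic regression. The resulting 2 × 3 = 6 base models are bagged with equal
weight: the ensemble class-probability vector is the arithmetic mean

    p̄ = (1/6) Σₖ pₖ,

and a case is called to the arg-max tissue only when max(p̄) clears a
confidence threshold (default 0.6); otherwise it is reported UNCLASSIFIED.
Profiles are library-size normalized to a fixed total and log1p-transformed;
mixing is always performed on the de-logged scale.

**Actionability tiering.** A deterministic rule engine matches each alteration
(mutation, amplification, homozygous deletion, fusion, outlier expression,
viral, diagnosis marker) against a frozen local knowledge base with explicit
evidence levels. Tier 1 = established clinical utility in that cancer type
(subcategories S somatic, R resistance, G germline — flagged G1\* when the gene
is a therapeutic target — and D diagnosis change); tier 2 = investigational /
off-label rationale or preclinical resistance; tier 3 = biological relevance
only. The strongest matching rule wins.

**Germline second hits.** PGVs are categorized as highly penetrant, moderately
penetrant, autosomal-recessive cancer-risk, or autosomal-recessive non-cancer
from an editable gene panel. Genes in double-strand-break repair (BRCA1, BRCA2,
ATM, PALB2, BRIP1) or mismatch repair (MLH1, MSH2, PMS2) are therapeutic
targets. A somatic mutation, homozygous deletion, or LOH event in the same gene
is a two-hit inactivation.

**Outcomes.** Clinical benefit = sequencing-directed therapy (SDT) held ≥ 6
months; exceptional response = ≥ 12 months; durations are exact day counts over
a 30.4375-day month. `cohort_rates` turns a cohort count table into headline
percentages with half-up rounding to one decimal.

## Worked example

`examples/05_clinical_outcomes.py` feeds a 1015-patient cohort's count table
through the rate computation:

```
183-day course = 6.01 months -> {'benefit': True, 'exceptional': False}
actionable_pct                  80.5%
sdt_initiation_pct              16.2%
clinical_benefit_pct            37.1%
exceptional_response_pct        19.7%
pgv_patient_pct                 15.8%
second_hit_pct                  40.8%
cup_reclassified_pct            50.9%
cup_benefit_pct                 53.8%
```

80.5% of patients carry at least one tier-1/2 (actionable) alteration; 16.2% of
those initiated SDT; 37.1% of SDT recipients stayed on therapy ≥ 6 months.
The CUP benefit rate (53.8% = 7/13) is computed per SDT *instance* because one
patient received two serial SDTs.

`examples/02_tissue_of_origin.py` trains the six-model ensemble on a synthetic
corpus (5 tissues × 40 samples, 200 genes, log-normal noise 0.5) and classifies
50 held-out biopsies contaminated with 20% of their own site's normal signal:

```
held-out samples at 20% contamination: 50
correct definitive calls: 50
unclassified (confidence < 0.6): 0
accuracy among classified: 1.000
```

The remaining examples cover cohort simulation, tier assignment, germline
second-hit summaries, and the seeded end-to-end pipeline
(`oncoprofile run-all --seed 7` from the shell, or `run_pipeline(RunConfig(...))`
from Python).

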