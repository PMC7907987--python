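# Methods

This note records the models, parameter choices, and numerical conventions
behind `oncoprofile`, and what the synthetic cohorts do and do not establish.

## Tissue-of-origin ensemble

### Model

Let `x` be a sample's nonnegative expression vector. Profiles are normalized
by library size to a fixed total of 10⁴ and transformed with `log1p`; all
classifier inputs live on this log scale. Biopsy contamination is modeled as
a physical mixture of transcripts, so admixing is done in linear space:

    mix(tumor, normal, α) = log1p((1 − α) · expm1(tumor) + α · expm1(normal))

with `α = 0` returning the tumor profile bit-for-bit.

Training sets are built under three schemes: **none** (profiles unmodified),
**biopsy-site** (each sample mixed with its own site's normal profile), and
**mean-all-sites** (mixed with the unweighted mean of the site normal
vectors). Each scheme is crossed with two learners — a ν-SVM (`NuSVC`,
linear kernel) and an L1-penalized multinomial logistic regression
(`LogisticRegressionCV`) — giving six base models that are bagged with equal
weight by averaging their probability vectors. The arg-max class is reported
only when the mean top probability reaches the confidence threshold;
otherwise the call is UNCLASSIFIED, which is the honest outcome for a CUP
whose expression matches no training tissue well.

### Parameters

| parameter | default | notes |
|---|---|---|
| contamination fraction α per training sample | Uniform(0, 0.5) | the admixture level of real biopsies is unobserved; spanning none-to-moderate contamination covers realistic tumor purity. One draw per sample. |
| ν (SVM margin/support-vector bound) | 0.25 | moderate margin softness; overridable via `hyperparams` |
| lasso penalty C | CV grid {0.01, 0.1, 1, 10}, 3 folds | chosen by internal cross-validation on each training rendering |
| confidence threshold | 0.6 | proportion in [0,1]; governs the UNCLASSIFIED rate and is deliberately a config knob |
| normalization target total | 10⁴ | counts-per-ten-thousand before log1p |

SVM probabilities come from the standard Platt-style calibration fitted on
internal training folds (`probability=True`); margin scores are not on a
probability scale and the ensemble needs a common one. Probabilities from
each member are re-ordered onto the shared sorted class-label list before
averaging, and ties in the arg-max resolve to the lexicographically first
tissue name, making predictions deterministic.

Two further conventions make training a pure function of (data, seed):
training samples are put into a canonical order (label, then feature bytes)
before fitting, so sample order is irrelevant; and all six members share one
fit seed while drawing per-member data substreams, so two schemes fed
identical data (e.g. any scheme with α ≡ 0) produce identical fitted models.
The "bag" is the six fixed (learner × scheme) models; optional bootstrap
resampling of each member's training set exists behind a flag but is off by
default, since the six-way model diversity is the aggregation of interest.
Probability averaging is used rather than vote counting; votes discard
exactly the calibrated confidence the UNCLASSIFIED gate needs.

Prediction requires the exact training gene order; a mismatched gene list is
a hard error rather than being imputed, because silent imputation hides
format bugs.

## Actionability tiering

Evidence levels map to tiers as: FDA-approved benefit → 1 S, FDA-approved
resistance → 1 R, investigational/off-label → 2 S, preclinical resistance →
2 R, biological-only → 3 S; a pathogenic or likely-pathogenic germline
variant matching a cancer-risk gene → 1 G (G1\* when the gene is a
therapeutic target); a diagnosis-marker alteration with a changed diagnosis
→ 1 D. Context matching is exact-string-or-ANY with no ontology traversal —
minimal and auditable. An FDA-approved rule matched outside its indication
degrades to tier 2 (off-label rationale). When several rules match, the
winner is chosen by (tier ascending, subcategory order G < D < S < R, entry
id), so assignment is total, deterministic, and monotone in evidence level:
upgrading a rule's evidence can only lower the tier. Unmatched alterations
fall to tier 3 with an empty rationale rather than erroring, since absence
from a knowledge base is a data state, not a failure.

The knowledge base is a frozen local TSV/JSON file. Live annotation
databases drift; reproducible tiering requires a pinned snapshot, and the
snapshot format doubles as the fixture format for tests.

## Germline analysis

The gene panel ships as an editable TSV mapping gene → predisposition
category; the therapeutic-target flag is *defined* by membership in the
DSB-repair set {BRCA1, BRCA2, ATM, PALB2, BRIP1} or the MMR set {MLH1, MSH2,
PMS2} and is forced accordingly. A second hit is any somatic mutation,
homozygous deletion, or LOH event in the PGV's gene. LOH enters as an
explicit event class in the somatic table rather than being derived from
allele fractions: allele-level analysis is out of scope, and an explicit
class keeps the call auditable from tabular inputs. Copy-neutral LOH is
therefore included whenever the upstream caller labels it `loh`.

Percentages throughout are rounded half-up to one decimal (`utils.percent`,
exact rational arithmetic), the convention used by clinical cohort tables;
Python's built-in banker's rounding would print 0.05 as 0.0.

## Clinical outcomes

Durations are exact day counts divided by 30.4375 days/month (365.25 / 12).
Benefit (≥ 6 months) and exceptional response (≥ 12 months) use inclusive
thresholds applied to the exact day-count arithmetic, not to rounded month
values. Ongoing courses are measured to a censor date; extending the censor
date can only lengthen durations. The CUP benefit rate supports a
per-instance unit (benefit courses / SDT courses) alongside the per-patient
unit, needed when patients receive serial SDTs. Best-response categories
(CR/PR/SD/PD/NE) are carried through reports but play no role in benefit
classification, which is purely duration-based.

## Synthetic cohorts

The expression generator emulates the structure the classifier relies on:
per-tissue log-normal expression (Gaussian log-values around a tissue mean,
exponentiated, hence nonnegative and right-skewed), disjoint 10-gene marker
blocks with a +2.0 log-unit effect, samples spread round-robin over biopsy
sites, and a per-site normal panel built as the mean of 20 dedicated normal
draws from a site-specific profile without tumor markers (mirroring the use
of separate normal-tissue compendia rather than tumor data). The clinical
generator plants actionable tiers against a bundled synthetic knowledge
base, PGVs from the bundled panel, second hits as same-gene somatic events,
and SDT durations from a mixture of short-exponential non-responders (mean 2
months) and uniform 6–40-month responders, so both benefit classes occur.
Planted flags use randomized rounding — exactly ⌊n·f⌋ (+1 with probability
equal to the fractional part) patients drawn at random — so the expected
prevalence equals the requested fraction and realized prevalence is within
one patient of it for every seed.

What passing tests on these cohorts shows: the pipeline recovers planted
truths under the stated noise and admixture model, and its arithmetic is
exact. What they do not show: performance on real compendium expression
(batch effects, correlated genes, overlapping marker programs, real gene
identifiers), real knowledge-base curation quality, or real clinical
endpoint noise. The number of tissue classes and training-set sizes of a
production tissue-of-origin model are free parameters here; the bundled
study conditions (5 tissues × 40 samples, 200 genes, noise 0.5, 3 sites)
are desk-scale choices that keep the full suite under half a minute while
leaving the classification task non-trivial at α up to 0.4. At cohort
level, the recovered actionable prevalence slightly exceeds the planted
somatic fraction because tier-1 germline calls add patients — the same
additivity the tiering schema has by design.

## Reproducibility conventions

Every public entry point that consumes randomness takes an integer seed;
multi-stage consumers (ensemble training, the pipeline) derive per-stage
substreams from one root `SeedSequence`, so a single seed reproduces a run
byte-for-byte. Model files are joblib binaries with a format-version field
and are run-time artifacts, not exchange formats. Pipeline runs write a
manifest with the config hash and package version.
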