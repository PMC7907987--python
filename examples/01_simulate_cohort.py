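"""Generate a seeded synthetic cohort: expression corpus plus clinical tables.

The corpus has 5 tissue classes with 10 marker genes each; the clinical
table plants actionable alterations, germline variants and therapy courses
at chosen rates. Everything is reproducible from the seed.
"""

import oncoprofile as op

corpus = op.generate_expression_corpus(
    n_tissues=5, n_sites=3, n_genes=200, n_per_tissue=40, noise_sd=0.5, seed=1
)
print(f"expression matrix: {corpus.expression.shape[0]} genes x {corpus.expression.shape[1]} samples")
print(f"tissues: {sorted(corpus.tissue_labels.unique())}")
print(f"normal panel sites: {list(corpus.normal_panel.columns)}")

table = op.generate_clinical_table(
    n_patients=1015,
    actionable_fraction=0.805,
    pgv_fraction=0.158,
    second_hit_fraction=0.408,
    seed=1,
)
truth = table.truth
print(f"\npatients: {len(table.patients)}")
print(f"planted actionable: {truth['actionable'].sum()} ({100 * truth['actionable'].mean():.1f}%)")
print(f"planted PGV carriers: {truth['has_pgv'].sum()} ({100 * truth['has_pgv'].mean():.1f}%)")
carriers = truth[truth["has_pgv"]]
print(
    f"planted second hits among carriers: {carriers['planted_second_hit'].sum()} "
    f"({100 * carriers['planted_second_hit'].mean():.1f}%)"
)
print("\nThe planted percentages track the requested fractions to within one")
print("patient; downstream stages must recover these truths from the tables.")
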