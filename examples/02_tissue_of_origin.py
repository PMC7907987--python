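"""Train the six-model tissue-of-origin ensemble and classify contaminated biopsies.

The ensemble pairs two learners (nu-SVM, multinomial lasso) with three
training-contamination schemes (none / biopsy-site normal / mean of all site
normals). Held-out samples are admixed with 20% normal signal from their own
biopsy site before prediction — the situation the contamination training is
designed to survive.
"""

import numpy as np

import oncoprofile as op
from oncoprofile.expression import contaminate_profile, normalize_profile, predict_tissue

corpus = op.generate_expression_corpus(5, 3, 200, 40, noise_sd=0.5, seed=1)
train, test = op.split_corpus(corpus, test_per_tissue=10)
model = op.train_ensemble(train, threshold=0.6, seed=11)
print("ensemble members:", [(m.learner.value, m.scheme.value) for m in model.members])

gene_ids = tuple(test.expression.index)
correct = total = unclassified = 0
for sample in test.expression.columns:
    site = test.site_labels[sample]
    profile = normalize_profile(test.expression[sample].to_numpy(), gene_ids, site)
    normal = normalize_profile(test.normal_panel[site].to_numpy(), gene_ids, site)
    pred = predict_tissue(model, contaminate_profile(profile, normal, 0.2))
    total += 1
    if pred.label == op.UNCLASSIFIED:
        unclassified += 1
    elif pred.label == test.tissue_labels[sample]:
        correct += 1

print(f"\nheld-out samples at 20% contamination: {total}")
print(f"correct definitive calls: {correct}")
print(f"unclassified (confidence < 0.6): {unclassified}")
print(f"accuracy among classified: {correct / max(total - unclassified, 1):.3f}")
print("\nA high accuracy here means the contamination-aware training absorbed")
print("the admixed normal-tissue signal instead of being misled by it.")
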