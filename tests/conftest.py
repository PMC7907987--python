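import numpy as np
import pytest
from hypothesis import settings

import oncoprofile as op
from oncoprofile.expression import aggregate_probabilities, contaminate_profile, normalize_profile

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")

# the standard synthetic study conditions used throughout
STD_CORPUS = dict(n_tissues=5, n_sites=3, n_genes=200, n_per_tissue=40, noise_sd=0.5, seed=1)
STD_TEST_PER_TISSUE = 10
STD_ENSEMBLE_SEED = 11


@pytest.fixture(scope="session")
def std_corpus():
    return op.generate_expression_corpus(**STD_CORPUS)


@pytest.fixture(scope="session")
def std_split(std_corpus):
    return op.split_corpus(std_corpus, STD_TEST_PER_TISSUE)


@pytest.fixture(scope="session")
def std_ensemble(std_split):
    train, _ = std_split
    return op.train_ensemble(train, seed=STD_ENSEMBLE_SEED)


def contaminated_test_profiles(test_corpus, alpha):
    """Held-out profiles admixed with their own biopsy site's normal signal."""
    gene_ids = tuple(test_corpus.expression.index)
    profiles, truths = [], []
    for sample in test_corpus.expression.columns:
        site = test_corpus.site_labels[sample]
        profile = normalize_profile(test_corpus.expression[sample].to_numpy(), gene_ids, site)
        normal = normalize_profile(test_corpus.normal_panel[site].to_numpy(), gene_ids, site)
        profiles.append(contaminate_profile(profile, normal, alpha))
        truths.append(test_corpus.tissue_labels[sample])
    return profiles, truths


def accuracy(members, class_labels, profiles, truths):
    """Arg-max accuracy of an equal-weight bag of members (no confidence gate)."""
    correct = 0
    for profile, truth in zip(profiles, truths):
        mean = aggregate_probabilities([m.predict_proba([profile])[0] for m in members])
        correct += class_labels[int(np.argmax(mean))] == truth
    return correct / len(profiles)
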