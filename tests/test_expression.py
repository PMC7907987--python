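"""Normalization, contamination mixing, base learners, and the six-model ensemble."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import oncoprofile as op
from oncoprofile.expression import (
    ContaminationScheme,
    ExpressionProfile,
    Learner,
    UNCLASSIFIED,
    aggregate_probabilities,
    build_training_set,
    contaminate_profile,
    fixed_alpha,
    normalize_profile,
    predict_tissue,
    train_base_model,
)
from oncoprofile.tiering import ValidationError


class TestNormalization:
    def test_all_zero_vector_stays_zero(self):
        profile = normalize_profile(np.zeros(5))
        assert np.all(profile.values == 0.0)

    def test_library_size_invariance(self):
        raw = np.array([1.0, 5.0, 14.0])
        a = normalize_profile(raw)
        b = normalize_profile(raw * 37.5)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_matches_hand_computation(self):
        # (0, 3, 9) scaled to total 1e4 -> (0, 2500, 7500), then log1p
        profile = normalize_profile(np.array([0.0, 3.0, 9.0]))
        np.testing.assert_allclose(
            profile.values, np.log1p([0.0, 2500.0, 7500.0]), rtol=1e-12
        )

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValidationError):
            normalize_profile(np.array([1.0, -0.5]))

    @given(
        arrays(np.float64, 6, elements=st.floats(0, 1e6)),
        st.floats(1.5, 100.0),
    )
    def test_scale_invariance_property(self, raw, factor):
        a = normalize_profile(raw)
        b = normalize_profile(raw * factor)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9, atol=1e-9)


def _profile(linear_values, site=None):
    genes = tuple(f"g{i}" for i in range(len(linear_values)))
    return ExpressionProfile(genes, np.log1p(np.asarray(linear_values, float)), site)


class TestContamination:
    def test_alpha_zero_is_identity(self):
        tumor, normal = _profile([10.0, 0.0]), _profile([0.0, 10.0])
        assert contaminate_profile(tumor, normal, 0.0) is tumor

    def test_alpha_one_is_pure_normal(self):
        tumor, normal = _profile([10.0, 0.0]), _profile([0.0, 10.0])
        mixed = contaminate_profile(tumor, normal, 1.0)
        np.testing.assert_allclose(mixed.values, normal.values, rtol=1e-12)

    def test_half_mixture_in_linear_space(self):
        mixed = contaminate_profile(_profile([10.0, 0.0]), _profile([0.0, 10.0]), 0.5)
        np.testing.assert_allclose(mixed.values, np.log1p([5.0, 5.0]), rtol=1e-12)

    def test_gene_mismatch_rejected(self):
        tumor = _profile([1.0, 2.0])
        normal = ExpressionProfile(("x", "y"), np.log1p([1.0, 2.0]))
        with pytest.raises(ValidationError):
            contaminate_profile(tumor, normal, 0.3)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            contaminate_profile(_profile([1.0]), _profile([2.0]), 1.5)

    @given(st.floats(0.0, 1.0))
    def test_mixture_interpolates_linearly(self, alpha):
        tumor, normal = _profile([8.0, 2.0, 0.0]), _profile([1.0, 1.0, 4.0])
        mixed = contaminate_profile(tumor, normal, alpha)
        expected = (1 - alpha) * np.array([8.0, 2.0, 0.0]) + alpha * np.array([1.0, 1.0, 4.0])
        np.testing.assert_allclose(np.expm1(mixed.values), expected, rtol=1e-9, atol=1e-9)


@pytest.fixture(scope="module")
def small_corpus():
    return op.generate_expression_corpus(3, 2, 60, 8, 0.4, seed=21)


class TestTrainingSets:
    def test_none_scheme_is_a_no_op(self, small_corpus):
        profiles, labels = build_training_set(small_corpus, ContaminationScheme.NONE, seed=0)
        gene_ids = tuple(small_corpus.expression.index)
        for sample, profile in zip(small_corpus.expression.columns, profiles):
            expected = normalize_profile(
                small_corpus.expression[sample].to_numpy(), gene_ids
            )
            np.testing.assert_array_equal(profile.values, expected.values)
        assert labels == list(small_corpus.tissue_labels)

    def test_single_site_schemes_coincide(self):
        corpus = op.generate_expression_corpus(2, 1, 30, 4, 0.3, seed=5)
        a, _ = build_training_set(corpus, ContaminationScheme.BIOPSY_SITE, fixed_alpha(0.3), 1)
        b, _ = build_training_set(corpus, ContaminationScheme.MEAN_ALL_SITES, fixed_alpha(0.3), 1)
        for pa, pb in zip(a, b):
            np.testing.assert_allclose(pa.values, pb.values, rtol=1e-12)

    def test_biopsy_site_scheme_matches_per_sample_oracle(self, small_corpus):
        profiles, _ = build_training_set(
            small_corpus, ContaminationScheme.BIOPSY_SITE, fixed_alpha(0.3), seed=0
        )
        gene_ids = tuple(small_corpus.expression.index)
        for sample, got in zip(small_corpus.expression.columns, profiles):
            site = small_corpus.site_labels[sample]
            tumor = normalize_profile(small_corpus.expression[sample].to_numpy(), gene_ids)
            normal = normalize_profile(small_corpus.normal_panel[site].to_numpy(), gene_ids)
            expected = contaminate_profile(tumor, normal, 0.3)
            np.testing.assert_allclose(got.values, expected.values, rtol=1e-12)

    def test_missing_site_in_panel_rejected(self, small_corpus):
        # a panel not covering every biopsy site is caught at corpus validation,
        # before any training set can be built from it
        with pytest.raises(ValidationError):
            dataclasses.replace(
                small_corpus, normal_panel=small_corpus.normal_panel.iloc[:, :1]
            )


def _separable_toy():
    genes = ("g0", "g1")
    profiles = [
        ExpressionProfile(genes, np.array([5.0, 0.1])),
        ExpressionProfile(genes, np.array([4.0, 0.3])),
        ExpressionProfile(genes, np.array([0.2, 5.0])),
        ExpressionProfile(genes, np.array([0.4, 4.0])),
    ]
    return profiles, ["a", "a", "b", "b"]


class TestBaseLearners:
    @pytest.mark.parametrize("learner", list(Learner))
    def test_separable_toy_fit_perfectly(self, learner):
        profiles, labels = _separable_toy()
        model = train_base_model(learner, (profiles, labels), {"cv": 2})
        probs = model.predict_proba(profiles)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        predicted = [model.class_labels[i] for i in probs.argmax(axis=1)]
        assert predicted == labels

    @pytest.mark.parametrize("learner", list(Learner))
    def test_single_class_rejected(self, learner):
        profiles, _ = _separable_toy()
        with pytest.raises(ValidationError):
            train_base_model(learner, (profiles, ["a"] * 4))

    @pytest.mark.parametrize("learner", list(Learner))
    def test_sample_order_invariance(self, learner, small_corpus):
        profiles, labels = build_training_set(small_corpus, ContaminationScheme.NONE, seed=0)
        model_a = train_base_model(learner, (profiles, labels), {"seed": 3, "cv": 2})
        perm = np.random.default_rng(0).permutation(len(profiles))
        shuffled = ([profiles[i] for i in perm], [labels[i] for i in perm])
        model_b = train_base_model(learner, shuffled, {"seed": 3, "cv": 2})
        probe = profiles[:5]
        np.testing.assert_allclose(
            model_a.predict_proba(probe), model_b.predict_proba(probe), atol=1e-6
        )

    def test_strong_lasso_penalty_induces_sparsity(self):
        """With duplicated informative features a strong L1 penalty zeroes most
        coefficients while training predictions match an unpenalized fit."""
        rng = np.random.default_rng(0)
        genes = tuple(f"g{i}" for i in range(20))
        base = rng.normal(0, 1, (30, 1))
        X = np.hstack([base + rng.normal(0, 0.01, base.shape) for _ in range(20)])
        labels = ["hi" if v > 0 else "lo" for v in base[:, 0]]
        profiles = [ExpressionProfile(genes, row + 5.0) for row in X]
        strong = train_base_model(
            Learner.MULTINOMIAL_LASSO, (profiles, labels), {"Cs": (0.2,), "cv": 2}
        )
        loose = train_base_model(
            Learner.MULTINOMIAL_LASSO, (profiles, labels), {"Cs": (100.0,), "cv": 2}
        )
        coef_strong = strong.pipeline.named_steps["clf"].coef_
        coef_loose = loose.pipeline.named_steps["clf"].coef_
        assert (coef_strong == 0).sum() > (coef_loose == 0).sum()
        for model in (strong, loose):
            probs = model.predict_proba(profiles)
            predicted = [model.class_labels[i] for i in probs.argmax(axis=1)]
            assert predicted == labels


@dataclasses.dataclass
class _StubMember:
    """A fake base model emitting fixed probability vectors, for aggregation tests."""

    learner: object
    scheme: object
    class_labels: tuple
    table: dict  # id(profile) -> probability vector

    def predict_proba(self, profiles):
        return np.asarray([self.table[id(p)] for p in profiles])


def _stub_ensemble(prob_vectors_per_member, profile, class_labels, threshold=0.6):
    members = [
        _StubMember(("learner", i), ("scheme", i), class_labels, {id(profile): v})
        for i, v in enumerate(prob_vectors_per_member)
    ]
    return op.EnsembleModel.__new__(op.EnsembleModel), members


class TestEnsemble:
    def test_member_set_is_two_learners_by_three_schemes(self, small_corpus):
        model = op.train_ensemble(small_corpus, seed=1, hyperparams={"cv": 2})
        pairs = {(m.learner, m.scheme) for m in model.members}
        assert pairs == set(
            (lrn, sch) for lrn in Learner for sch in ContaminationScheme
        )
        assert len(model.members) == 6

    def test_single_tissue_corpus_rejected(self):
        corpus = op.generate_expression_corpus(1, 1, 10, 4, 0.2, seed=0)
        with pytest.raises(ValidationError):
            op.train_ensemble(corpus, seed=0)

    def test_seeded_determinism_on_probe(self, small_corpus):
        probe = normalize_profile(
            small_corpus.expression.iloc[:, 0].to_numpy(),
            tuple(small_corpus.expression.index),
        )
        a = op.train_ensemble(small_corpus, seed=9, hyperparams={"cv": 2})
        b = op.train_ensemble(small_corpus, seed=9, hyperparams={"cv": 2})
        pa, pb = predict_tissue(a, probe), predict_tissue(b, probe)
        np.testing.assert_array_equal(pa.probabilities.values, pb.probabilities.values)
        assert pa.label == pb.label

    def test_alpha_zero_contaminated_members_equal_none_members(self, small_corpus):
        model = op.train_ensemble(
            small_corpus, alpha_sampler=fixed_alpha(0.0), seed=4, hyperparams={"cv": 2}
        )
        probes, _ = build_training_set(small_corpus, ContaminationScheme.NONE, seed=0)
        probes = probes[:6]
        by_key = {(m.learner, m.scheme): m for m in model.members}
        for learner in Learner:
            reference = by_key[(learner, ContaminationScheme.NONE)].predict_proba(probes)
            for scheme in (ContaminationScheme.BIOPSY_SITE, ContaminationScheme.MEAN_ALL_SITES):
                np.testing.assert_allclose(
                    by_key[(learner, scheme)].predict_proba(probes), reference, atol=1e-6
                )


class TestPrediction:
    def _make_model(self, member_probs, class_labels, threshold=0.6):
        profile = _profile([1.0, 2.0, 3.0])
        members = [
            _StubMember(("L", i % 2), ("S", i), class_labels, {id(profile): np.asarray(v)})
            for i, v in enumerate(member_probs)
        ]
        model = op.EnsembleModel.__new__(op.EnsembleModel)
        model.members = members
        model.class_labels = class_labels
        model.confidence_threshold = threshold
        return model, profile

    def test_unanimous_members(self):
        model, profile = self._make_model(
            [[0.0, 1.0, 0.0]] * 6, ("kidney", "lung", "prostate")
        )
        pred = predict_tissue(model, profile)
        assert pred.label == "lung" and pred.confidence == 1.0

    def test_mirror_tie_breaks_lexicographically(self):
        probs = [[0.9, 0.1]] * 3 + [[0.1, 0.9]] * 3
        model, profile = self._make_model(probs, ("alpha", "beta"), threshold=0.5)
        pred = predict_tissue(model, profile)
        assert pred.confidence == pytest.approx(0.5)
        assert pred.label == "alpha"
        gated, profile2 = self._make_model(probs, ("alpha", "beta"), threshold=0.6)
        assert predict_tissue(gated, profile2).label == UNCLASSIFIED

    def test_aggregation_matches_brute_force_mean(self):
        rng = np.random.default_rng(12)
        raw = rng.random((6, 4))
        raw /= raw.sum(axis=1, keepdims=True)
        brute = sum(raw[i] for i in range(6)) / 6.0
        np.testing.assert_allclose(aggregate_probabilities(list(raw)), brute, atol=1e-12)

    def test_probabilities_sum_to_one(self, small_corpus):
        model = op.train_ensemble(small_corpus, seed=2, hyperparams={"cv": 2})
        probe = normalize_profile(
            small_corpus.expression.iloc[:, 5].to_numpy(),
            tuple(small_corpus.expression.index),
        )
        pred = predict_tissue(model, probe)
        assert pred.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert ((pred.probabilities >= 0) & (pred.probabilities <= 1)).all()

    def test_gene_mismatch_rejected(self, small_corpus):
        model = op.train_ensemble(small_corpus, seed=2, hyperparams={"cv": 2})
        with pytest.raises(ValidationError):
            predict_tissue(model, _profile([1.0, 2.0]))


class TestCohortClassification:
    def _counting_model(self, confident_profiles, vague_profiles):
        class_labels = ("hepatic", "pulmonary")
        table = {}
        for p in confident_profiles:
            table[id(p)] = np.array([0.9, 0.1])
        for p in vague_profiles:
            table[id(p)] = np.array([0.5, 0.5])
        members = [
            _StubMember(("L", i % 2), ("S", i), class_labels, table) for i in range(6)
        ]
        model = op.EnsembleModel.__new__(op.EnsembleModel)
        model.members = members
        model.class_labels = class_labels
        model.confidence_threshold = 0.6
        return model

    def test_planted_resolvable_cup_cases_counted(self):
        confident = [_profile([float(i + 1), 1.0]) for i in range(28)]
        vague = [_profile([1.0, float(i + 1)]) for i in range(27)]
        model = self._counting_model(confident, vague)
        cases = [(p, "CUP") for p in confident + vague]
        report = op.classify_cohort(model, cases)
        assert report["reclassified"].sum() == 28
        assert report.attrs["reclassified_fraction"] == pytest.approx(28 / 55)

    def test_agreeing_prior_diagnosis_not_reclassified(self):
        confident = [_profile([2.0, 1.0])]
        model = self._counting_model(confident, [])
        report = op.classify_cohort(model, [(confident[0], "hepatic")])
        assert not report["reclassified"].any()

    def test_all_unclassified_gives_zero_fraction(self):
        vague = [_profile([1.0, float(i + 2)]) for i in range(4)]
        model = self._counting_model([], vague)
        report = op.classify_cohort(model, [(p, "CUP") for p in vague])
        assert report.attrs["reclassified_fraction"] == 0.0

    def test_empty_case_set_rejected(self):
        model = self._counting_model([_profile([2.0, 1.0])], [])
        with pytest.raises(ValidationError):
            op.classify_cohort(model, [])
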