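"""Tissue-of-origin estimation for carcinomas of unknown primary (CUP).

Metastatic biopsies are impure: the tumor signal is mixed with transcripts
from the normal tissue at the biopsy site. A classifier trained on pure
primary-tumor expression therefore degrades on real biopsies. The estimator
here counters that with *training-set contamination*: labeled tumor profiles
are admixed, in linear expression space, with normal-tissue expression before
model fitting.

Three contamination schemes are used — none, the sample's own biopsy-site
normal profile, and the unweighted mean of all site normal profiles — and two
learners, a nu-parameterized support-vector machine and an L1-penalized
(lasso) multinomial logistic regression. The 2 x 3 combinations give six base
models that are bagged with equal weight: the ensemble's class probabilities
are the arithmetic mean of the members' probability vectors. A prediction
whose top mean probability falls below a confidence threshold is reported as
UNCLASSIFIED rather than forced to a tissue label.

Profiles are library-size normalized to a fixed total and log1p-transformed;
mixing is always done on the de-logged scale because contamination is a
physical mixture of transcripts, not of log values.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import product
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import NuSVC

from .tiering import ValidationError
from .utils import MAX_SEED, derive_seed

UNCLASSIFIED = "UNCLASSIFIED"
TARGET_TOTAL = 1e4  # library-size normalization target


class ContaminationScheme(Enum):
    """How training examples are admixed with normal-tissue expression."""

    NONE = "none"
    BIOPSY_SITE = "biopsy_site"
    MEAN_ALL_SITES = "mean_all_sites"


class Learner(Enum):
    NU_SUPPORT_VECTOR = "nu_svm"
    MULTINOMIAL_LASSO = "lasso"


@dataclass(frozen=True)
class ExpressionProfile:
    """One sample's normalized (log1p) expression vector in fixed gene order."""

    gene_ids: tuple[str, ...]
    values: np.ndarray
    site: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != len(self.gene_ids):
            raise ValidationError("values must be one number per gene id")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must be finite")


@dataclass(frozen=True)
class MixtureFraction:
    """Proportion of normal-tissue signal admixed into a tumor profile."""

    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must lie in [0, 1], got {self.alpha}")


def normalize_profile(
    raw_counts: Sequence[float] | np.ndarray,
    gene_ids: Sequence[str] | None = None,
    site: str | None = None,
    target_total: float = TARGET_TOTAL,
) -> ExpressionProfile:
    """Library-size scale nonnegative abundances to ``target_total``, then log1p.

    Two samples differing only by a global scale factor normalize to the same
    profile. An all-zero vector stays all zero.
    """
    raw = np.asarray(raw_counts, dtype=float)
    if np.any(raw < 0):
        raise ValidationError("abundances must be nonnegative")
    if gene_ids is None:
        gene_ids = tuple(f"G{i:05d}" for i in range(len(raw)))
    total = raw.sum()
    # divide first: raw/total is bounded by 1, so tiny totals cannot overflow
    scaled = (raw / total) * target_total if total > 0 else raw
    return ExpressionProfile(tuple(gene_ids), np.log1p(scaled), site)


def contaminate_profile(
    tumor: ExpressionProfile,
    normal: ExpressionProfile,
    frac: MixtureFraction | float,
) -> ExpressionProfile:
    """Mix tumor and normal profiles at proportion alpha in linear space.

    Both profiles are de-logged, combined as (1 - alpha) * tumor +
    alpha * normal, and re-logged. alpha = 0 returns the tumor profile
    unchanged; alpha = 1 returns the normal values (with the tumor's site
    label kept, since the biopsy site is a property of the specimen).
    """
    alpha = frac.alpha if isinstance(frac, MixtureFraction) else MixtureFraction(frac).alpha
    if tumor.gene_ids != normal.gene_ids:
        raise ValidationError("tumor and normal profiles must share gene ids")
    if alpha == 0.0:
        return tumor
    mixed = (1.0 - alpha) * np.expm1(tumor.values) + alpha * np.expm1(normal.values)
    return ExpressionProfile(tumor.gene_ids, np.log1p(mixed), tumor.site)


AlphaSampler = Callable[[np.random.Generator], float]


def uniform_alpha(low: float = 0.0, high: float = 0.5) -> AlphaSampler:
    """Default contamination sampler: one uniform draw per training sample."""
    MixtureFraction(low), MixtureFraction(high)
    return lambda rng: float(rng.uniform(low, high))


def fixed_alpha(alpha: float) -> AlphaSampler:
    MixtureFraction(alpha)
    return lambda rng: alpha


def _normal_profiles(corpus) -> dict[str, ExpressionProfile]:
    """Per-site normalized normal profiles from the corpus's raw normal panel."""
    gene_ids = tuple(corpus.expression.index)
    return {
        site: normalize_profile(corpus.normal_panel[site].to_numpy(), gene_ids, site)
        for site in corpus.normal_panel.columns
    }


def _mean_normal_profile(corpus) -> ExpressionProfile:
    # unweighted mean of the site normal vectors, taken on the raw scale
    gene_ids = tuple(corpus.expression.index)
    mean_raw = corpus.normal_panel.to_numpy().mean(axis=1)
    return normalize_profile(mean_raw, gene_ids)


def build_training_set(
    corpus,
    scheme: ContaminationScheme,
    alpha_sampler: AlphaSampler | None = None,
    seed: int = 0,
) -> tuple[list[ExpressionProfile], list[str]]:
    """Normalize every corpus sample and apply one contamination scheme.

    NONE leaves profiles unmodified; BIOPSY_SITE mixes each sample with its
    own site's normal profile; MEAN_ALL_SITES mixes with the mean normal
    profile over all sites. Tissue labels are preserved. One alpha is drawn
    per sample from ``alpha_sampler`` (default uniform on [0, 0.5]).
    """
    if alpha_sampler is None:
        alpha_sampler = uniform_alpha()
    rng = np.random.default_rng(seed)
    gene_ids = tuple(corpus.expression.index)
    site_normals = _normal_profiles(corpus) if scheme != ContaminationScheme.NONE else {}
    mean_normal = (
        _mean_normal_profile(corpus) if scheme == ContaminationScheme.MEAN_ALL_SITES else None
    )
    profiles: list[ExpressionProfile] = []
    labels: list[str] = []
    for sample in corpus.expression.columns:
        site = corpus.site_labels[sample]
        profile = normalize_profile(corpus.expression[sample].to_numpy(), gene_ids, site)
        if scheme == ContaminationScheme.BIOPSY_SITE:
            if site not in site_normals:
                raise ValidationError(f"site {site!r} missing from normal panel")
            profile = contaminate_profile(profile, site_normals[site], alpha_sampler(rng))
        elif scheme == ContaminationScheme.MEAN_ALL_SITES:
            profile = contaminate_profile(profile, mean_normal, alpha_sampler(rng))
        profiles.append(profile)
        labels.append(corpus.tissue_labels[sample])
    return profiles, labels


@dataclass
class BaseModel:
    """One fitted learner under one contamination scheme."""

    learner: Learner
    scheme: ContaminationScheme
    pipeline: Pipeline
    class_labels: tuple[str, ...]
    gene_ids: tuple[str, ...]

    def predict_proba(self, profiles: Sequence[ExpressionProfile]) -> np.ndarray:
        X = _stack(profiles, self.gene_ids)
        raw = self.pipeline.predict_proba(X)
        # align estimator class order to the shared sorted label order
        order = [list(self.pipeline.classes_).index(c) for c in self.class_labels]
        return raw[:, order]


def _stack(profiles: Sequence[ExpressionProfile], gene_ids: tuple[str, ...]) -> np.ndarray:
    rows = []
    for p in profiles:
        if p.gene_ids != gene_ids:
            raise ValidationError("profile gene ids do not match training gene order")
        rows.append(p.values)
    return np.asarray(rows)


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deterministic sample order (label, then feature bytes) so fitting is
    invariant to the order training examples arrive in."""
    keys = [(y[i], X[i].tobytes()) for i in range(len(y))]
    return np.asarray(sorted(range(len(y)), key=keys.__getitem__))


def train_base_model(
    learner: Learner,
    training: tuple[Sequence[ExpressionProfile], Sequence[str]],
    hyperparams: Mapping | None = None,
    scheme: ContaminationScheme = ContaminationScheme.NONE,
) -> BaseModel:
    """Fit one base classifier emitting calibrated class probabilities.

    The support-vector learner obtains probabilities through the standard
    Platt-style calibration fitted on internal training folds; the lasso
    learner selects its penalty on a cross-validated grid. Training samples
    are first put into a canonical order so results do not depend on input
    ordering.
    """
    hp = dict(hyperparams or {})
    profiles, labels = training
    y = np.asarray(list(labels))
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValidationError("training requires at least two tissue classes")
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise ValidationError("training requires at least two samples per class")
    gene_ids = profiles[0].gene_ids
    X = _stack(profiles, gene_ids)
    order = _canonical_order(X, y)
    X, y = X[order], y[order]
    seed = int(hp.get("seed", 0)) % MAX_SEED

    if learner is Learner.NU_SUPPORT_VECTOR:
        clf = NuSVC(
            nu=float(hp.get("nu", 0.25)),
            kernel=hp.get("kernel", "linear"),
            probability=True,
            random_state=seed,
        )
    elif learner is Learner.MULTINOMIAL_LASSO:
        clf = LogisticRegressionCV(
            Cs=hp.get("Cs", (0.01, 0.1, 1.0, 10.0)),
            penalty="l1",
            solver="saga",
            cv=int(hp.get("cv", 3)),
            max_iter=int(hp.get("max_iter", 5000)),
            tol=float(hp.get("tol", 1e-4)),
            random_state=seed,
        )
    else:
        raise ValidationError(f"unknown learner {learner!r}")

    pipeline = Pipeline([("scale", StandardScaler()), ("clf", clf)])
    pipeline.fit(X, y)
    return BaseModel(learner, scheme, pipeline, tuple(classes), gene_ids)


@dataclass(frozen=True)
class ToOPrediction:
    """One tissue-of-origin call: label (or UNCLASSIFIED) plus probabilities."""

    label: str
    probabilities: pd.Series  # indexed by class label, sums to 1
    confidence: float


@dataclass
class EnsembleModel:
    """Six equally weighted base models: 2 learners x 3 contamination schemes."""

    members: list[BaseModel]
    class_labels: tuple[str, ...]
    confidence_threshold: float = 0.6

    def __post_init__(self) -> None:
        pairs = {(m.learner, m.scheme) for m in self.members}
        if len(pairs) != len(self.members):
            raise ValidationError("ensemble members must be distinct (learner, scheme) pairs")
        for m in self.members:
            if m.class_labels != self.class_labels:
                raise ValidationError("all members must share the same class labels")
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValidationError("confidence threshold must lie in [0, 1]")


def aggregate_probabilities(member_probs: Sequence[np.ndarray]) -> np.ndarray:
    """Equal-weight bagging: the arithmetic mean of member probability vectors."""
    stacked = np.asarray(member_probs, dtype=float)
    return stacked.mean(axis=0)


def train_ensemble(
    corpus,
    alpha_sampler: AlphaSampler | None = None,
    hyperparams: Mapping | None = None,
    threshold: float = 0.6,
    seed: int = 0,
    bootstrap: bool = False,
) -> EnsembleModel:
    """Fit the six-member ensemble on one corpus.

    One member per (learner, contamination scheme) pair, each trained on its
    own contaminated rendering of the corpus. ``bootstrap=True`` additionally
    resamples each member's training set with replacement (off by default:
    the six fixed model types are themselves the bag).
    """
    classes = sorted(set(corpus.tissue_labels))
    if len(classes) < 2:
        raise ValidationError("corpus must contain at least two tissue classes")
    root = np.random.SeedSequence(seed)
    members: list[BaseModel] = []
    combos = list(product(Learner, ContaminationScheme))
    children = root.spawn(len(combos) + 1)
    # one fit seed shared by all members: identical training data must yield
    # identical fitted models regardless of which scheme produced the data
    fit_seed = derive_seed(children[0])
    for child, (learner, scheme) in zip(children[1:], combos):
        data_seed, boot_seed = (derive_seed(s) for s in child.spawn(2))
        try:
            profiles, labels = build_training_set(corpus, scheme, alpha_sampler, data_seed)
            if bootstrap:
                rng = np.random.default_rng(boot_seed)
                idx = rng.integers(0, len(profiles), size=len(profiles))
                profiles = [profiles[i] for i in idx]
                labels = [labels[i] for i in idx]
            hp = dict(hyperparams or {})
            hp["seed"] = fit_seed
            member = train_base_model(learner, (profiles, labels), hp, scheme)
        except ValidationError as err:
            raise ValidationError(
                f"member ({learner.value}, {scheme.value}): {err}"
            ) from err
        members.append(member)
    return EnsembleModel(members, tuple(classes), threshold)


def predict_tissue(model: EnsembleModel, profile: ExpressionProfile) -> ToOPrediction:
    """Ensemble call for one profile.

    Probabilities are the unweighted mean over the six members; the label is
    the arg-max class (ties broken by lexicographic class name, which is the
    order classes are stored in), demoted to UNCLASSIFIED when the top mean
    probability is below the confidence threshold.
    """
    member_probs = [m.predict_proba([profile])[0] for m in model.members]
    mean = aggregate_probabilities(member_probs)
    top = int(np.argmax(mean))  # first index wins ties = lexicographic class
    confidence = float(mean[top])
    label = model.class_labels[top] if confidence >= model.confidence_threshold else UNCLASSIFIED
    return ToOPrediction(label, pd.Series(mean, index=list(model.class_labels)), confidence)


def save_model(model: EnsembleModel, path) -> None:
    """Persist a fitted ensemble (joblib binary; a run-time artifact)."""
    import joblib

    joblib.dump({"format_version": 1, "model": model}, path)


def load_model(path) -> EnsembleModel:
    import joblib

    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValidationError("unsupported model file version")
    return payload["model"]


def profiles_from_tsv(
    path, labels_path=None
) -> tuple[list[ExpressionProfile], pd.DataFrame | None]:
    """Read raw gene x sample abundances from TSV and normalize each column.

    ``labels_path`` optionally points to a sample/tissue/site table; site
    labels, when present, are attached to the profiles.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", index_col=0) if labels_path else None
    gene_ids = tuple(frame.index)
    profiles = []
    for sample in frame.columns:
        site = None
        if labels is not None and sample in labels.index and "site" in labels.columns:
            site = labels.loc[sample, "site"]
        profiles.append(normalize_profile(frame[sample].to_numpy(), gene_ids, site))
    return profiles, labels


CUP_LABEL = "CUP"


def classify_cohort(
    model: EnsembleModel,
    cases: Sequence[tuple[ExpressionProfile, str]],
) -> pd.DataFrame:
    """Classify a cohort of (profile, prior diagnosis) cases.

    A case counts as *reclassified* when the ensemble returns a definitive
    label (not UNCLASSIFIED) that resolves a CUP or differs from the prior
    diagnosis. The returned frame carries one row per case plus the
    reclassified fraction in ``frame.attrs["reclassified_fraction"]``.
    """
    if not cases:
        raise ValidationError("empty case set")
    rows = []
    for i, (profile, prior) in enumerate(cases):
        pred = predict_tissue(model, profile)
        reclassified = pred.label != UNCLASSIFIED and (prior == CUP_LABEL or prior != pred.label)
        rows.append(
            {
                "case": i,
                "prior_diagnosis": prior,
                "predicted": pred.label,
                "confidence": pred.confidence,
                "reclassified": reclassified,
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["reclassified_fraction"] = float(frame["reclassified"].mean())
    return frame
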