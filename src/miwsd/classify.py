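"""Sense classification: RBF-kernel SVM over signed-weight vectors, plus the
most-frequent-sense baseline.

The core learner contract is binary: fit on labeled vectors, return a signed
decision margin.  A positive margin (including exactly zero, the documented
tie rule) predicts the designated positive sense.  Words with more than two
senses are reduced one-vs-rest, each submodel running its own sense-vs-rest
feature selection; prediction is the argmax of submodel margins.

An optional abstention threshold (default 0, i.e. always predict) withholds
the prediction when the deciding margin's magnitude falls below it.

The SVM is scikit-learn's ``SVC`` with its default parameters and the RBF
kernel (C = 1.0, gamma = "scale"); the resolved hyperparameters are recorded
in the trained model for reproducibility.  Any margin-producing binary
learner satisfying the same fit/decide contract can stand in.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.svm import SVC

from .corpus import Instance, LabeledCorpus, NONE_SENSE
from .errors import MiwsdError, ValidationError
from .features import FeatureModel, count_contingency, select_features
from .preprocess import ContextBag, PreprocessConfig, extract_context
from .vectorize import vectorize

__all__ = [
    "Prediction",
    "SvmLearner",
    "BinarySubmodel",
    "TrainedModel",
    "MfsModel",
    "train",
    "predict",
    "mfs_baseline",
    "save_model",
    "load_model",
]

_ARCHIVE_VERSION = 1


@dataclass(frozen=True)
class Prediction:
    """Predicted sense for one instance; ``None`` means abstained."""

    instance_id: str
    predicted_sense: str | None
    margin: float


class SvmLearner:
    """Default binary learner: RBF-kernel SVC with library defaults."""

    def __init__(self) -> None:
        self._svc = SVC(kernel="rbf")
        self.params = {"kernel": "rbf", "C": self._svc.C, "gamma": self._svc.gamma}

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SvmLearner":
        """y is +1 for the positive sense, -1 otherwise."""
        self._svc.fit(X, y)
        return self

    def decide(self, X: np.ndarray) -> np.ndarray:
        """Signed margins; positive favours the positive sense."""
        # sklearn orders classes_ ascending, so decision_function > 0 <=> +1
        return np.asarray(self._svc.decision_function(X), dtype=float)


@dataclass
class BinarySubmodel:
    feature_model: FeatureModel
    learner: SvmLearner
    positive_label: str
    negative_label: str


@dataclass
class TrainedModel:
    """A fitted sense classifier (binary core or one-vs-rest reduction)."""

    config: PreprocessConfig
    senses: list[str]
    reduction: str  # "binary" | "one_vs_rest"
    submodels: list[BinarySubmodel]
    abstain_threshold: float = 0.0
    learner_params: dict = field(default_factory=dict)

    @property
    def fingerprint(self) -> str:
        return self.config.fingerprint()


def _class_bags(
    corpus: LabeledCorpus, config: PreprocessConfig
) -> dict[str, list[ContextBag]]:
    return {
        sense: [extract_context(inst, config) for inst in corpus.classes[sense]]
        for sense in corpus.senses
    }


def _fit_binary(
    pos_bags: Sequence[ContextBag],
    neg_bags: Sequence[ContextBag],
    positive: str,
    negative: str,
    scorer: str,
    k: int,
    fingerprint: str,
) -> BinarySubmodel:
    counts = count_contingency(pos_bags, neg_bags)
    fmodel = select_features(counts, scorer=scorer, k=k, fingerprint=fingerprint)
    X = np.vstack(
        [vectorize(b, fmodel).values for b in list(pos_bags) + list(neg_bags)]
    )
    y = np.concatenate([np.ones(len(pos_bags)), -np.ones(len(neg_bags))])
    try:
        learner = SvmLearner().fit(X, y)
    except Exception as exc:  # pragma: no cover - defensive wrap
        raise MiwsdError(f"learner failed to fit: {exc}") from exc
    return BinarySubmodel(fmodel, learner, positive, negative)


def train(
    corpus: LabeledCorpus,
    scorer: str = "mi",
    k: int = 200,
    config: PreprocessConfig | None = None,
    seed: int = 0,
    abstain_threshold: float = 0.0,
) -> TrainedModel:
    """Fit the full pipeline: preprocessing -> feature selection -> SVM.

    With two senses a single binary model is fitted (the lexicographically
    first sense is the positive class); with more, one-vs-rest submodels,
    each with its own sense-vs-rest feature selection.  Deterministic given
    the corpus and configuration; ``seed`` is accepted for interface
    symmetry (the pipeline itself draws no random numbers).
    """
    config = config or PreprocessConfig()
    senses = corpus.senses
    if NONE_SENSE in senses:
        raise ValidationError(
            'corpus contains "none"-labeled instances; filter eligibility first'
        )
    if len(senses) < 2:
        raise ValidationError(f"need >= 2 senses to train, got {len(senses)}")
    for sense in senses:
        if len(corpus.classes[sense]) < 1:
            raise ValidationError(f"sense {sense!r} has no instances")
    bags = _class_bags(corpus, config)
    fp = config.fingerprint()

    if len(senses) == 2:
        pos, neg = senses
        sub = _fit_binary(bags[pos], bags[neg], pos, neg, scorer, k, fp)
        submodels = [sub]
        reduction = "binary"
    else:
        submodels = []
        for sense in senses:
            rest: list[ContextBag] = []
            for other in senses:
                if other != sense:
                    rest.extend(bags[other])
            submodels.append(
                _fit_binary(bags[sense], rest, sense, "<rest>", scorer, k, fp)
            )
        reduction = "one_vs_rest"

    return TrainedModel(
        config=config,
        senses=senses,
        reduction=reduction,
        submodels=submodels,
        abstain_threshold=abstain_threshold,
        learner_params=submodels[0].learner.params,
    )


def _margins(model: TrainedModel, bag: ContextBag) -> list[float]:
    out = []
    for sub in model.submodels:
        x = vectorize(bag, sub.feature_model).values.reshape(1, -1)
        out.append(float(sub.learner.decide(x)[0]))
    return out


def predict(model: TrainedModel, instances: Sequence[Instance]) -> list[Prediction]:
    """Disambiguate instances with a fitted model.

    Binary: the sign of the margin picks the sense (zero -> positive label).
    One-vs-rest: argmax of submodel margins, ties to the lexicographically
    first sense.  Abstains when the deciding margin's magnitude is below the
    configured threshold.
    """
    preds: list[Prediction] = []
    for inst in instances:
        bag = extract_context(inst, model.config)
        margins = _margins(model, bag)
        if model.reduction == "binary":
            margin = margins[0]
            sub = model.submodels[0]
            sense = sub.positive_label if margin >= 0 else sub.negative_label
        else:
            best = int(np.argmax(margins))  # argmax keeps the first of ties;
            # submodels are in sorted-sense order, so ties already resolve
            # to the lexicographically first sense
            margin = margins[best]
            sense = model.submodels[best].positive_label
        if abs(margin) < model.abstain_threshold:
            preds.append(Prediction(inst.id, None, margin))
        else:
            preds.append(Prediction(inst.id, sense, margin))
    return preds


@dataclass
class MfsModel:
    """Constant classifier: always the training-majority sense."""

    majority_sense: str

    def predict(self, instances: Sequence[Instance]) -> list[Prediction]:
        return [Prediction(inst.id, self.majority_sense, 0.0) for inst in instances]


def mfs_baseline(train_corpus: LabeledCorpus) -> MfsModel:
    """Most-frequent-sense baseline; ties broken lexicographically."""
    sizes = train_corpus.class_sizes()
    sizes.pop(NONE_SENSE, None)
    if not sizes:
        raise ValidationError("no annotated senses to take a majority over")
    majority = min(sizes, key=lambda s: (-sizes[s], s))
    return MfsModel(majority_sense=majority)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model (versioned archive with config fingerprint)."""
    joblib.dump(
        {
            "archive_version": _ARCHIVE_VERSION,
            "fingerprint": model.fingerprint,
            "model": model,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    """Load a trained model; refuses on version or fingerprint mismatch."""
    payload = joblib.load(path)
    if payload.get("archive_version") != _ARCHIVE_VERSION:
        raise ValidationError(
            f"unsupported model archive version {payload.get('archive_version')!r}"
        )
    model: TrainedModel = payload["model"]
    if model.config.fingerprint() != payload["fingerprint"]:
        raise ValidationError(
            "model archive fingerprint does not match its preprocessing config"
        )
    return model
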