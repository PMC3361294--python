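"""Cross-validated evaluation: accuracy, the most-frequent-sense baseline,
and micro/macro precision-recall-F1 for the species disambiguation task.

Accuracy for a fold is

    accuracy = correct predictions / total tested instances

and the reported figure is the unweighted mean over folds, even when fold
sizes differ by one.  Folds are stratified (each fold's class proportions
match the corpus within one instance) and deterministic per seed.

Precision counts only issued predictions in its denominator; recall counts
all test instances.  With abstention disabled the two coincide (and equal
accuracy), so micro P = R = F1 — the distinction only matters when an
abstention threshold withholds low-margin predictions.

Species entities are cross-validated per entity with the fold count set by
the scarcest species: exactly 3 occurrences -> 3 repeats (2 train / 1 test
per species), exactly 4 -> leave-one-out over that species (4 folds), 5 or
more -> standard 5-fold CV.  Instance-level outcomes are pooled across
entities for the micro averages; macro averages are computed per entity and
then averaged.  Species metrics are reported as percentages.
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify import Prediction, mfs_baseline, predict, train
from .corpus import Instance, LabeledCorpus, NONE_SENSE, corpus_from_instances
from .errors import ValidationError
from .preprocess import PreprocessConfig

__all__ = [
    "FoldPlan",
    "EvalSettings",
    "FoldMetrics",
    "EvaluationReport",
    "make_folds",
    "cross_validate",
    "species_evaluate",
]


@dataclass(frozen=True)
class EvalSettings:
    """Evaluation configuration (defaults are the method's headline setting:
    MI scorer, k = 200, window = 5, 5-fold CV)."""

    scorer: str = "mi"
    k: int = 200
    config: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_folds: int = 5
    seed: int = 0
    abstain_threshold: float = 0.0

    def echo(self) -> dict[str, Any]:
        return {
            "scorer": self.scorer,
            "k": self.k,
            "window": self.config.window,
            "stem": self.config.stem,
            "lowercase": self.config.lowercase,
            "window_prefilter": self.config.window_prefilter,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "abstain_threshold": self.abstain_threshold,
            "config_fingerprint": self.config.fingerprint(),
        }


@dataclass(frozen=True)
class FoldPlan:
    """A stratified partition of instance ids into folds."""

    n_folds: int
    assignments: dict[str, int]
    stratified: bool
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [iid for iid, f in self.assignments.items() if f == fold]


def make_folds(corpus: LabeledCorpus, n_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified fold assignment, deterministic per seed.

    Every class must have at least ``n_folds`` instances so each fold can
    hold a stratified share of it.
    """
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    for sense, size in corpus.class_sizes().items():
        if size < n_folds:
            raise ValidationError(
                f"sense {sense!r} has {size} instances; need >= {n_folds} for "
                f"{n_folds}-fold stratified CV"
            )
    instances = corpus.instances()
    y = [inst.sense for inst in instances]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        for i in test_idx:
            assignments[instances[i].id] = fold
    return FoldPlan(n_folds=n_folds, assignments=assignments, stratified=True, seed=seed)


@dataclass(frozen=True)
class FoldMetrics:
    fold: int
    n_test: int
    n_issued: int
    n_correct: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    baseline_accuracy: float | None = None


def _prf(n_correct: int, n_issued: int, n_test: int) -> tuple[float, float, float]:
    precision = n_correct / n_issued if n_issued else 0.0
    recall = n_correct / n_test if n_test else 0.0
    if precision == recall:  # exact identity (e.g. abstention disabled)
        f1 = precision
    elif (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
    return precision, recall, f1


def _score_fold(
    predictions: list[Prediction], truth: Mapping[str, str]
) -> tuple[int, int, int]:
    """Return (n_correct, n_issued, n_test)."""
    n_test = len(predictions)
    issued = [p for p in predictions if p.predicted_sense is not None]
    n_correct = sum(1 for p in issued if p.predicted_sense == truth[p.instance_id])
    return n_correct, len(issued), n_test


@dataclass
class EvaluationReport:
    """Per-fold and aggregate results of one evaluation run."""

    folds: list[FoldMetrics]
    mean_accuracy: float
    baseline_accuracy: float | None
    micro_precision: float
    micro_recall: float
    micro_f1: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n_instances: int
    settings: dict[str, Any]
    scale: float = 1.0  # 1.0 = fractions, 100.0 = percentages

    def to_json(self) -> str:
        payload = {
            "settings": self.settings,
            "n_instances": self.n_instances,
            "scale": self.scale,
            "mean_accuracy": self.mean_accuracy,
            "baseline_accuracy": self.baseline_accuracy,
            "micro": {
                "precision": self.micro_precision,
                "recall": self.micro_recall,
                "f1": self.micro_f1,
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "folds": [asdict(f) for f in self.folds],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def to_text(self) -> str:
        lines = ["fold  accuracy  precision  recall      F1" + (
            "  baseline" if self.baseline_accuracy is not None else "")]
        for f in self.folds:
            row = (
                f"{f.fold + 1:>4}  {f.accuracy:8.3f}  {f.precision:9.3f}  "
                f"{f.recall:6.3f}  {f.f1:6.3f}"
            )
            if f.baseline_accuracy is not None:
                row += f"  {f.baseline_accuracy:8.3f}"
            lines.append(row)
        lines.append(
            f"mean  {self.mean_accuracy:8.3f}  {self.micro_precision:9.3f}  "
            f"{self.micro_recall:6.3f}  {self.micro_f1:6.3f}"
            + (
                f"  {self.baseline_accuracy:8.3f}"
                if self.baseline_accuracy is not None
                else ""
            )
        )
        lines.append(f"instances tested: {self.n_instances}")
        return "\n".join(lines)


def _split_corpus(
    corpus: LabeledCorpus, plan: FoldPlan, fold: int
) -> tuple[LabeledCorpus, list[Instance]]:
    train_insts: list[Instance] = []
    test_insts: list[Instance] = []
    for inst in corpus.instances():
        (test_insts if plan.assignments[inst.id] == fold else train_insts).append(inst)
    return corpus_from_instances(train_insts), test_insts


def cross_validate(corpus: LabeledCorpus, settings: EvalSettings | None = None) -> EvaluationReport:
    """Stratified k-fold cross-validation of the full pipeline on one word.

    Each fold trains on the remaining folds (feature selection included, so
    no test-time leakage) and is also scored against the most-frequent-sense
    baseline fitted on the identical training split.
    """
    settings = settings or EvalSettings()
    if NONE_SENSE in corpus.classes:
        raise ValidationError(
            'corpus contains "none"-labeled instances; filter eligibility first'
        )
    if len(corpus.classes) < 2:
        raise ValidationError("need >= 2 senses to evaluate")
    plan = make_folds(corpus, settings.n_folds, settings.seed)
    truth = {inst.id: inst.sense for inst in corpus.instances()}

    folds: list[FoldMetrics] = []
    per_class: dict[str, dict[str, int]] = {
        s: {"correct": 0, "issued_as": 0, "truth_n": 0} for s in corpus.senses
    }
    total_correct = total_issued = total_test = 0
    for fold in range(plan.n_folds):
        train_corpus, test_insts = _split_corpus(corpus, plan, fold)
        try:
            model = train(
                train_corpus,
                scorer=settings.scorer,
                k=settings.k,
                config=settings.config,
                seed=settings.seed,
                abstain_threshold=settings.abstain_threshold,
            )
        except ValidationError as exc:
            raise ValidationError(f"fold {fold}: {exc}") from exc
        preds = predict(model, test_insts)
        n_correct, n_issued, n_test = _score_fold(preds, truth)
        precision, recall, f1 = _prf(n_correct, n_issued, n_test)
        baseline = mfs_baseline(train_corpus)
        base_preds = baseline.predict(test_insts)
        base_correct, _, _ = _score_fold(base_preds, truth)
        folds.append(
            FoldMetrics(
                fold=fold,
                n_test=n_test,
                n_issued=n_issued,
                n_correct=n_correct,
                accuracy=n_correct / n_test,
                precision=precision,
                recall=recall,
                f1=f1,
                baseline_accuracy=base_correct / n_test,
            )
        )
        total_correct += n_correct
        total_issued += n_issued
        total_test += n_test
        for p in preds:
            if p.predicted_sense is not None:
                per_class[p.predicted_sense]["issued_as"] += 1
                if p.predicted_sense == truth[p.instance_id]:
                    per_class[p.predicted_sense]["correct"] += 1
        for inst in test_insts:
            per_class[inst.sense]["truth_n"] += 1

    micro_p, micro_r, micro_f1 = _prf(total_correct, total_issued, total_test)
    # macro over sense labels for the single-word task
    macro_parts = [
        _prf(v["correct"], v["issued_as"], v["truth_n"]) for v in per_class.values()
    ]
    macro_p = float(np.mean([p for p, _, _ in macro_parts]))
    macro_r = float(np.mean([r for _, r, _ in macro_parts]))
    macro_f1 = float(np.mean([f for _, _, f in macro_parts]))

    return EvaluationReport(
        folds=folds,
        mean_accuracy=float(np.mean([f.accuracy for f in folds])),
        baseline_accuracy=float(np.mean([f.baseline_accuracy for f in folds])),
        micro_precision=micro_p,
        micro_recall=micro_r,
        micro_f1=micro_f1,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=macro_f1,
        n_instances=total_test,
        settings=settings.echo(),
    )


def _entity_n_folds(corpus: LabeledCorpus) -> int:
    """Fold count from the scarcest species: 3 -> 3 repeats, 4 -> LOO, >=5 -> 5FCV."""
    return min(5, min(corpus.class_sizes().values()))


def species_evaluate(
    corpora: Mapping[str, LabeledCorpus], settings: EvalSettings | None = None
) -> EvaluationReport:
    """Evaluate species disambiguation over a collection of entities.

    Instance-level outcomes are pooled across entities by fold index for the
    per-fold and overall micro averages; macro averages are per entity, then
    averaged.  All metrics are percentages.
    """
    settings = settings or EvalSettings()
    if not corpora:
        raise ValidationError("no eligible entities to evaluate")
    max_folds = 0
    pooled: dict[int, list[int]] = {}
    entity_stats: list[tuple[int, int, int]] = []
    for entity in sorted(corpora):
        corpus = corpora[entity]
        n_folds = _entity_n_folds(corpus)
        max_folds = max(max_folds, n_folds)
        plan = make_folds(corpus, n_folds, settings.seed)
        truth = {inst.id: inst.sense for inst in corpus.instances()}
        e_correct = e_issued = e_test = 0
        for fold in range(n_folds):
            train_corpus, test_insts = _split_corpus(corpus, plan, fold)
            model = train(
                train_corpus,
                scorer=settings.scorer,
                k=settings.k,
                config=settings.config,
                seed=settings.seed,
                abstain_threshold=settings.abstain_threshold,
            )
            preds = predict(model, test_insts)
            n_correct, n_issued, n_test = _score_fold(preds, truth)
            bucket = pooled.setdefault(fold, [0, 0, 0])
            bucket[0] += n_correct
            bucket[1] += n_issued
            bucket[2] += n_test
            e_correct += n_correct
            e_issued += n_issued
            e_test += n_test
        entity_stats.append((e_correct, e_issued, e_test))

    folds: list[FoldMetrics] = []
    total_correct = total_issued = total_test = 0
    for fold in range(max_folds):
        n_correct, n_issued, n_test = pooled[fold]
        precision, recall, f1 = _prf(n_correct, n_issued, n_test)
        folds.append(
            FoldMetrics(
                fold=fold,
                n_test=n_test,
                n_issued=n_issued,
                n_correct=n_correct,
                accuracy=100.0 * n_correct / n_test,
                precision=100.0 * precision,
                recall=100.0 * recall,
                f1=100.0 * f1,
            )
        )
        total_correct += n_correct
        total_issued += n_issued
        total_test += n_test

    micro_p, micro_r, micro_f1 = _prf(total_correct, total_issued, total_test)
    macro_parts = [_prf(c, i, t) for c, i, t in entity_stats]
    return EvaluationReport(
        folds=folds,
        mean_accuracy=float(np.mean([f.accuracy for f in folds])),
        baseline_accuracy=None,
        micro_precision=100.0 * micro_p,
        micro_recall=100.0 * micro_r,
        micro_f1=100.0 * micro_f1,
        macro_precision=100.0 * float(np.mean([p for p, _, _ in macro_parts])),
        macro_recall=100.0 * float(np.mean([r for _, r, _ in macro_parts])),
        macro_f1=100.0 * float(np.mean([f for _, _, f in macro_parts])),
        n_instances=total_test,
        settings=settings.echo(),
        scale=100.0,
    )
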