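"""Context-word contingency counting and MI / M2 feature scoring.

For every context word w in the union vocabulary W of a two-class training
corpus, four counts are taken over the training examples:

    a — class-1 examples containing w        c — class-1 examples lacking w
    b — class-2 examples containing w        d — class-2 examples lacking w

and two discriminativeness scores are defined (N = total examples):

    MI = N * a / ((a + b) * (a + c))          (mutual-information style)
    M2 = (a + d) / (b + c)                    (agreement / disagreement ratio)

Counting is example-level presence by default, which keeps the identities
a + c = |C1| and b + d = |C2|.  A per-occurrence toggle counts a and b as
total occurrences instead (c and d stay example-level, as defined above).

When b + c = 0 the M2 denominator is replaced by 0.5, keeping the score
finite while preserving the ordering (a perfectly discriminative word
scores above any word with b + c >= 1).

The top-k words by score form the fitted :class:`FeatureModel`.  Scores are
frozen at fit time; unseen test-time vocabulary never updates the model.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

from .errors import ValidationError
from .preprocess import ContextBag

__all__ = [
    "ContingencyCounts",
    "FeatureModel",
    "count_contingency",
    "score_mi",
    "score_m2",
    "score",
    "select_features",
    "save_feature_model",
    "load_feature_model",
]

_SCORERS = ("mi", "m2")
_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ContingencyCounts:
    """Per-word contingency counts against the two classes."""

    word: str
    a: int
    b: int
    c: int
    d: int
    N: int

    def validate_presence_mode(self, n1: int, n2: int) -> None:
        if self.a + self.c != n1 or self.b + self.d != n2:
            raise ValidationError(
                f"word {self.word!r}: counts ({self.a},{self.b},{self.c},{self.d}) "
                f"inconsistent with class sizes ({n1},{n2})"
            )


def count_contingency(
    positive_bags: Sequence[ContextBag],
    negative_bags: Sequence[ContextBag],
    per_occurrence: bool = False,
) -> list[ContingencyCounts]:
    """Count (a, b, c, d) for every word in the union vocabulary.

    ``positive_bags`` are the class-1 training examples, ``negative_bags``
    class-2.  Returns one entry per distinct word, sorted by word.
    """
    if not positive_bags or not negative_bags:
        raise ValidationError("both classes must be non-empty to count contingencies")
    n1, n2 = len(positive_bags), len(negative_bags)
    N = n1 + n2
    a_examples: dict[str, int] = {}
    b_examples: dict[str, int] = {}
    a_occ: dict[str, int] = {}
    b_occ: dict[str, int] = {}
    for bag in positive_bags:
        for word, count in bag.words.items():
            a_examples[word] = a_examples.get(word, 0) + 1
            a_occ[word] = a_occ.get(word, 0) + count
    for bag in negative_bags:
        for word, count in bag.words.items():
            b_examples[word] = b_examples.get(word, 0) + 1
            b_occ[word] = b_occ.get(word, 0) + count
    vocabulary = sorted(set(a_examples) | set(b_examples))
    out = []
    for word in vocabulary:
        ae = a_examples.get(word, 0)
        be = b_examples.get(word, 0)
        a = a_occ.get(word, 0) if per_occurrence else ae
        b = b_occ.get(word, 0) if per_occurrence else be
        out.append(
            ContingencyCounts(word=word, a=a, b=b, c=n1 - ae, d=n2 - be, N=N)
        )
    return out


def score_mi(counts: ContingencyCounts) -> float:
    """MI = N * a / ((a + b) * (a + c)); 0 when the word never occurs in C1."""
    if counts.a + counts.b <= 0:
        raise ValidationError(
            f"word {counts.word!r} occurs in neither class (a + b = 0)"
        )
    if counts.a + counts.c <= 0:
        raise ValidationError("class C1 is empty (a + c = 0)")
    return counts.N * counts.a / ((counts.a + counts.b) * (counts.a + counts.c))


def score_m2(counts: ContingencyCounts) -> float:
    """M2 = (a + d) / (b + c), with denominator 0.5 when b + c = 0."""
    denom = counts.b + counts.c
    return (counts.a + counts.d) / (denom if denom > 0 else 0.5)


def score(counts: ContingencyCounts, scorer: str) -> float:
    if scorer == "mi":
        return score_mi(counts)
    if scorer == "m2":
        return score_m2(counts)
    raise ValidationError(f"unknown scorer {scorer!r} (expected one of {_SCORERS})")


@dataclass(frozen=True)
class FeatureModel:
    """The fitted vocabulary: top-k context words with their signed weights."""

    scorer: str
    k: int
    features: tuple[tuple[str, float], ...]
    fingerprint: str = ""

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(w for w, _ in self.features)

    @property
    def scores(self) -> tuple[float, ...]:
        return tuple(s for _, s in self.features)

    def __len__(self) -> int:
        return len(self.features)


def select_features(
    counts: Sequence[ContingencyCounts],
    scorer: str = "mi",
    k: int = 200,
    fingerprint: str = "",
) -> FeatureModel:
    """Rank all words by score and keep the top k.

    Ties are broken by descending total presence (a + b), then by word, so
    the selection is deterministic and independent of input order.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if not counts:
        raise ValidationError("empty vocabulary: nothing to select features from")
    scored = [(c.word, score(c, scorer), c.a + c.b) for c in counts]
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    features = tuple((w, s) for w, s, _ in scored[:k])
    return FeatureModel(scorer=scorer, k=k, features=features, fingerprint=fingerprint)


def save_feature_model(model: FeatureModel, path: str | Path) -> None:
    """Write the model as versioned JSON (bit-exact reload)."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "scorer": model.scorer,
        "k": model.k,
        "fingerprint": model.fingerprint,
        "features": [[w, s] for w, s in model.features],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_feature_model(path: str | Path) -> FeatureModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported feature-model format version {payload.get('format_version')!r}"
        )
    return FeatureModel(
        scorer=payload["scorer"],
        k=payload["k"],
        fingerprint=payload["fingerprint"],
        features=tuple((w, float(s)) for w, s in payload["features"]),
    )
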