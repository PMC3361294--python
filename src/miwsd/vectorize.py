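"""Signed-weight feature vectors.

Each instance is encoded as a dense vector over the fitted feature model:
entry i is +score_i when the i-th ranked feature word occurs in the
instance's context bag and -score_i otherwise.  Presence is bag membership
(>= 1 occurrence); repeat counts never scale an entry, and no further
normalization is applied before the learner.  M2-selected models are
encoded the same way with +/-M2 weights.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import LabeledCorpus
from .errors import ValidationError
from .features import FeatureModel
from .preprocess import ContextBag, PreprocessConfig, extract_context

__all__ = ["FeatureVector", "vectorize", "vectorize_corpus", "to_matrix", "write_svmlight"]


@dataclass(frozen=True)
class FeatureVector:
    """Dense signed-weight encoding of one instance."""

    instance_id: str
    values: np.ndarray
    label: str | None = None


def vectorize(bag: ContextBag, model: FeatureModel) -> FeatureVector:
    """Encode one context bag against the fitted feature model."""
    if len(model) == 0:
        raise ValidationError("cannot vectorize with an empty feature model")
    values = np.array(
        [s if w in bag else -s for w, s in model.features], dtype=float
    )
    return FeatureVector(instance_id=bag.instance_id, values=values)


def vectorize_corpus(
    corpus: LabeledCorpus,
    model: FeatureModel,
    config: PreprocessConfig,
    labeled: bool = True,
) -> list[FeatureVector]:
    """One vector per instance, in the corpus's deterministic order."""
    out = []
    for inst in corpus.instances():
        bag = extract_context(inst, config)
        vec = vectorize(bag, model)
        if labeled:
            vec = FeatureVector(vec.instance_id, vec.values, label=inst.sense)
        out.append(vec)
    return out


def to_matrix(vectors: Sequence[FeatureVector]) -> tuple[np.ndarray, list[str | None]]:
    """Stack vectors into an (n, k) design matrix plus the label list."""
    X = np.vstack([v.values for v in vectors])
    return X, [v.label for v in vectors]


def write_svmlight(
    vectors: Sequence[FeatureVector],
    path: str | Path,
    label_map: dict[str, int] | None = None,
) -> None:
    """Export in the sparse ``label index:value`` text format of SVM tools.

    Vectors are dense by construction, so every index 1..k is written.
    Unlabeled vectors get label 0.
    """
    lines = []
    for v in vectors:
        label = 0 if v.label is None else (label_map or {}).get(v.label, 0)
        entries = " ".join(f"{i + 1}:{x:g}" for i, x in enumerate(v.values))
        lines.append(f"{label} {entries}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
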