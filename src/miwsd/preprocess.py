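"""Text normalization and context-window extraction.

The pipeline is: lowercase -> tokenize on non-alphanumeric boundaries ->
remove stopwords -> Porter-stem.  No length-based token filtering and no
part-of-speech information is used; tokens inside parentheses or brackets
are kept, as are pure-digit tokens.

For each occurrence of the (normalized) target term the ``window`` tokens
immediately left and right form the context; an instance's context bag is
the multiset union over its occurrences.  By default the window is counted
over the normalized (post-stopword, post-stem) token sequence so that it
always contains content words; set ``window_prefilter=True`` to count the
window over raw tokens before filtering instead.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field

from ._tokens import split_tokens
from .corpus import Instance
from .errors import ContextError, ValidationError
from .porter import stem as porter_stem
from .stopwords import DEFAULT_STOPWORDS

__all__ = ["PreprocessConfig", "ContextBag", "tokenize", "normalize", "extract_context"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Normalization and windowing parameters.

    ``window`` is the number of context tokens taken on each side of a
    target occurrence (the method's headline setting is 5).
    """

    window: int = 5
    stopword_list: frozenset[str] = field(default=DEFAULT_STOPWORDS)
    stem: bool = True
    lowercase: bool = True
    window_prefilter: bool = False

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValidationError("window must be >= 1")

    def fingerprint(self) -> str:
        """Stable hash identifying the preprocessing behaviour."""
        payload = json.dumps(
            {
                "window": self.window,
                "stopwords": sorted(self.stopword_list),
                "stem": self.stem,
                "lowercase": self.lowercase,
                "window_prefilter": self.window_prefilter,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ContextBag:
    """Multiset of processed context tokens around one instance's target."""

    instance_id: str
    words: Counter

    def __contains__(self, word: str) -> bool:
        return self.words[word] > 0

    @property
    def size(self) -> int:
        return sum(self.words.values())


def tokenize(text: str, lowercase: bool = True) -> list[str]:
    """Split raw text into tokens on non-alphanumeric boundaries."""
    return split_tokens(text, lowercase=lowercase)


def normalize(tokens: list[str], config: PreprocessConfig) -> list[str]:
    """Remove stopwords, then Porter-stem (when enabled); order preserved."""
    kept = [t for t in tokens if t not in config.stopword_list]
    if config.stem:
        kept = [porter_stem(t) for t in kept]
    return kept


def _normalized_target(target: str, config: PreprocessConfig) -> list[str]:
    """The target as a token subsequence under the same normalization."""
    tokens = tokenize(target, lowercase=config.lowercase)
    if config.stem:
        tokens = [porter_stem(t) for t in tokens]
    if not tokens:
        raise ValidationError(f"target {target!r} normalizes to nothing")
    return tokens


def _find_occurrences(tokens: list[str], needle: list[str]) -> list[int]:
    n = len(needle)
    return [i for i in range(len(tokens) - n + 1) if tokens[i : i + n] == needle]


def extract_context(instance: Instance, config: PreprocessConfig) -> ContextBag:
    """Build the context bag for one instance.

    Every occurrence of the target contributes up to ``window`` tokens on
    each side (truncated at document edges); the bag is the multiset union
    over occurrences.  Target tokens themselves never enter the bag.
    """
    raw = tokenize(instance.text, lowercase=config.lowercase)
    target_tokens = _normalized_target(instance.target, config)

    if config.window_prefilter:
        # window measured in raw tokens, filtering applied afterwards
        raw_target = tokenize(instance.target, lowercase=config.lowercase)
        occurrences = _find_occurrences(raw, raw_target)
        span = len(raw_target)
        bag: Counter = Counter()
        for pos in occurrences:
            window_tokens = (
                raw[max(0, pos - config.window) : pos]
                + raw[pos + span : pos + span + config.window]
            )
            bag.update(normalize(window_tokens, config))
    else:
        tokens = normalize(raw, config)
        occurrences = _find_occurrences(tokens, target_tokens)
        span = len(target_tokens)
        bag = Counter()
        for pos in occurrences:
            bag.update(tokens[max(0, pos - config.window) : pos])
            bag.update(tokens[pos + span : pos + span + config.window])

    if not occurrences:
        raise ContextError(
            f"target {instance.target!r} not found in text after normalization",
            instance_id=instance.id,
        )
    # occurrences of the target adjacent to another occurrence would put
    # target tokens in a window; drop them from the bag
    for t in set(target_tokens):
        if t in bag:
            del bag[t]
    return ContextBag(instance_id=instance.id, words=bag)
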