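"""Sense-annotated corpora: domain types, native file I/O, eligibility
filters, and the synthetic corpus generator.

A corpus holds every annotated occurrence-bearing document ("instance") of
one ambiguous target term, partitioned by sense label.  The reserved label
``"none"`` marks instances the annotators left unsense-tagged; they are
kept on disk but excluded from training and scoring by the eligibility
filter.

Native file format
------------------
Line-delimited UTF-8 with four tab-separated fields per record::

    id <TAB> target <TAB> sense <TAB> text

Tabs, newlines, carriage returns and backslashes inside ``text`` are
backslash-escaped (``\\t``, ``\\n``, ``\\r``, ``\\\\``).  An optional header
line ``id\\ttarget\\tsense\\ttext`` is auto-detected.  Users holding licensed
corpora (e.g. sense-tagged MEDLINE abstracts or species-annotated entity
mentions) convert them to this format with any adapter that emits one
record per annotated document.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from ._tokens import split_tokens
from .errors import CorpusFormatError, ValidationError

__all__ = [
    "NONE_SENSE",
    "Instance",
    "LabeledCorpus",
    "GeneratorSpec",
    "Eligibility",
    "read_corpus",
    "read_instances",
    "write_corpus",
    "corpus_from_instances",
    "read_species_corpora",
    "filter_eligible_senses",
    "filter_species_entities",
    "generate_corpus",
    "planted_words",
    "shuffle_labels",
]

#: Reserved sense label for instances without an annotated sense.
NONE_SENSE = "none"

_HEADER = ("id", "target", "sense", "text")


@dataclass(frozen=True)
class Instance:
    """One sense-annotated document containing the ambiguous target term."""

    id: str
    target: str
    sense: str
    text: str

    def validate(self) -> None:
        if not self.sense:
            raise ValidationError(f"instance {self.id!r}: empty sense label")
        if not _contains_target(self.text, self.target):
            raise ValidationError(
                f"instance {self.id!r}: text does not contain target {self.target!r}"
            )


def _contains_target(text: str, target: str) -> bool:
    """Case-insensitive token-subsequence containment of target in text."""
    t_tokens = split_tokens(target)
    if not t_tokens:
        return False
    tokens = split_tokens(text)
    n = len(t_tokens)
    return any(tokens[i : i + n] == t_tokens for i in range(len(tokens) - n + 1))


@dataclass
class LabeledCorpus:
    """All instances of one target term, grouped by sense (the classes C1, C2, ...)."""

    target: str
    classes: dict[str, list[Instance]]

    @property
    def N(self) -> int:
        return sum(len(v) for v in self.classes.values())

    @property
    def senses(self) -> list[str]:
        return sorted(self.classes)

    def instances(self) -> list[Instance]:
        """All instances in a deterministic order: sorted sense, then input order."""
        out: list[Instance] = []
        for sense in self.senses:
            out.extend(self.classes[sense])
        return out

    def class_sizes(self) -> dict[str, int]:
        return {s: len(v) for s, v in self.classes.items()}

    def validate(self) -> None:
        seen: set[str] = set()
        for sense, insts in self.classes.items():
            for inst in insts:
                if inst.target != self.target:
                    raise ValidationError(
                        f"instance {inst.id!r}: target {inst.target!r} != corpus "
                        f"target {self.target!r}"
                    )
                if inst.sense != sense:
                    raise ValidationError(
                        f"instance {inst.id!r}: filed under sense {sense!r} but "
                        f"labeled {inst.sense!r}"
                    )
                if inst.id in seen:
                    raise ValidationError(f"duplicate instance id {inst.id!r}")
                seen.add(inst.id)
                inst.validate()


def corpus_from_instances(instances: Iterable[Instance]) -> LabeledCorpus:
    """Group instances (all sharing one target) into a LabeledCorpus."""
    classes: dict[str, list[Instance]] = {}
    target: str | None = None
    for inst in instances:
        if target is None:
            target = inst.target
        elif inst.target != target:
            raise ValidationError(
                f"mixed targets in one corpus: {target!r} vs {inst.target!r} "
                f"(instance {inst.id!r})"
            )
        classes.setdefault(inst.sense, []).append(inst)
    if target is None:
        raise ValidationError("cannot build a corpus from zero instances")
    return LabeledCorpus(target=target, classes=classes)


# ---------------------------------------------------------------------------
# Native file I/O
# ---------------------------------------------------------------------------

_ESCAPES = {"\\": "\\\\", "\t": "\\t", "\n": "\\n", "\r": "\\r"}


def _escape(s: str) -> str:
    for raw, esc in _ESCAPES.items():
        s = s.replace(raw, esc)
    return s


def _unescape(s: str, line: int) -> str:
    out: list[str] = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "\\":
            if i + 1 >= len(s):
                raise CorpusFormatError("dangling backslash escape", line)
            nxt = s[i + 1]
            mapped = {"\\": "\\", "t": "\t", "n": "\n", "r": "\r"}.get(nxt)
            if mapped is None:
                raise CorpusFormatError(f"unknown escape \\{nxt}", line)
            out.append(mapped)
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def read_instances(path: str | Path) -> list[Instance]:
    """Parse a native instance file into validated records (any mix of targets)."""
    path = Path(path)
    # split on newline only: escaped text may hold other control characters
    lines = path.read_text(encoding="utf-8").split("\n")
    instances: list[Instance] = []
    for lineno, raw in enumerate(lines, start=1):
        raw = raw.removesuffix("\r")
        if not raw.strip():
            continue
        if lineno == 1 and tuple(raw.split("\t")) == _HEADER:
            continue
        fields = raw.split("\t")
        if len(fields) != 4:
            raise CorpusFormatError(
                f"expected 4 tab-separated fields, got {len(fields)}", lineno
            )
        iid, target, sense, text = (_unescape(f, lineno) for f in fields)
        if not iid:
            raise CorpusFormatError("empty instance id", lineno)
        inst = Instance(id=iid, target=target, sense=sense, text=text)
        try:
            inst.validate()
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from exc
        instances.append(inst)
    return instances


def read_corpus(path: str | Path) -> LabeledCorpus:
    """Read a native instance file whose records all share one target term."""
    instances = read_instances(path)
    if not instances:
        raise ValidationError(f"{path}: no records")
    corpus = corpus_from_instances(instances)
    corpus.validate()
    return corpus


def write_corpus(corpus: LabeledCorpus, path: str | Path, header: bool = True) -> None:
    """Serialize a corpus to the native format (round-trips with read_corpus)."""
    path = Path(path)
    lines: list[str] = []
    if header:
        lines.append("\t".join(_HEADER))
    for inst in corpus.instances():
        lines.append(
            "\t".join(_escape(f) for f in (inst.id, inst.target, inst.sense, inst.text))
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_species_corpora(path: str | Path) -> dict[str, LabeledCorpus]:
    """Read a per-entity corpus collection.

    ``path`` may be a directory of native files (one entity per file) or a
    single native file mixing several targets; records are grouped by target
    either way.
    """
    path = Path(path)
    files = sorted(path.glob("*.tsv")) if path.is_dir() else [path]
    by_target: dict[str, list[Instance]] = {}
    for f in files:
        for inst in read_instances(f):
            by_target.setdefault(inst.target, []).append(inst)
    corpora = {t: corpus_from_instances(insts) for t, insts in sorted(by_target.items())}
    for c in corpora.values():
        c.validate()
    return corpora


# ---------------------------------------------------------------------------
# Eligibility filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Eligibility:
    """Outcome of the eligibility filter: ineligibility is routine, not an error."""

    eligible: bool
    corpus: LabeledCorpus | None
    reason: str = ""


def filter_eligible_senses(
    corpus: LabeledCorpus, min_instances_per_sense: int = 2
) -> Eligibility:
    """Apply the evaluation eligibility rule for one ambiguous word.

    Un-annotated (``"none"``-labeled) instances are removed, then senses with
    fewer than ``min_instances_per_sense`` remaining instances are removed.
    The word is eligible only if at least two senses survive.
    """
    if min_instances_per_sense < 1:
        raise ValidationError("min_instances_per_sense must be >= 1")
    kept = {
        sense: insts
        for sense, insts in corpus.classes.items()
        if sense != NONE_SENSE and len(insts) >= min_instances_per_sense
    }
    if len(kept) < 2:
        return Eligibility(
            eligible=False,
            corpus=None,
            reason=(
                f"{corpus.target!r}: {len(kept)} sense(s) with >= "
                f"{min_instances_per_sense} annotated instances (need >= 2)"
            ),
        )
    return Eligibility(True, LabeledCorpus(corpus.target, kept))


def filter_species_entities(
    corpora: Mapping[str, LabeledCorpus], min_species: int = 2, min_occ: int = 3
) -> dict[str, LabeledCorpus]:
    """Keep entities occurring in >= min_species species, >= min_occ times each.

    Within a kept entity, species classes below ``min_occ`` are dropped.
    """
    if min_species < 2:
        raise ValidationError("min_species must be >= 2")
    if min_occ < 1:
        raise ValidationError("min_occ must be >= 1")
    out: dict[str, LabeledCorpus] = {}
    for entity, corpus in corpora.items():
        kept = {
            sp: insts
            for sp, insts in corpus.classes.items()
            if sp != NONE_SENSE and len(insts) >= min_occ
        }
        if len(kept) >= min_species:
            out[entity] = LabeledCorpus(corpus.target, kept)
    return out


# ---------------------------------------------------------------------------
# Synthetic corpus generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic sense-annotated corpus.

    Each sense owns a disjoint set of "planted" cue words that appear in an
    instance's context with probability ``p_in`` when the instance carries
    that sense and ``p_out`` otherwise; a shared background vocabulary
    appears independently of the sense.  All emitted tokens are lowercase,
    stopword-free and fixed points of the Porter stemmer, so the planted
    structure survives preprocessing unchanged.
    """

    n_senses: int = 2
    instances_per_sense: int = 50
    planted_words_per_sense: int = 5
    p_in: float = 0.9
    p_out: float = 0.1
    background_vocab_size: int = 15
    background_word_prob: float = 0.25
    context_len: int = 5
    seed: int = 0
    target: str = "targetw0"

    def validate(self) -> None:
        if self.n_senses < 2:
            raise ValidationError("n_senses must be >= 2")
        for name in ("instances_per_sense", "planted_words_per_sense",
                     "background_vocab_size", "context_len"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValidationError("require 0 <= p_out < p_in <= 1")
        if not (0.0 <= self.background_word_prob <= 1.0):
            raise ValidationError("background_word_prob must be in [0, 1]")

    @property
    def senses(self) -> list[str]:
        return [f"sense{i}" for i in range(1, self.n_senses + 1)]


#: Neutral padding token used to fill contexts up to ``context_len`` a side.
_FILLER = "pad0"


def planted_words(spec: GeneratorSpec) -> dict[str, list[str]]:
    """Ground-truth cue vocabulary per sense (disjoint across senses)."""
    return {
        sense: [f"cue{i}n{j}" for j in range(spec.planted_words_per_sense)]
        for i, sense in enumerate(spec.senses, start=1)
    }


def _background_vocab(spec: GeneratorSpec) -> list[str]:
    return [f"bg{j}" for j in range(spec.background_vocab_size)]


def generate_corpus(spec: GeneratorSpec) -> LabeledCorpus:
    """Generate a deterministic synthetic corpus under ``spec``.

    Every instance embeds the target once, with ``context_len`` tokens on
    each side: sampled planted cue words sit innermost (sense-indicative
    vocabulary clusters near the ambiguous term, which is the premise of
    windowed context methods), then sampled background words, then neutral
    filler padding outermost.  A context window of at least ``context_len``
    post-filter tokens therefore captures every present planted word; if
    more than ``2 * context_len`` words are sampled present, the excess
    background words extend the context beyond ``context_len``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    planted = planted_words(spec)
    background = _background_vocab(spec)
    classes: dict[str, list[Instance]] = {s: [] for s in spec.senses}
    counter = 0
    for sense in spec.senses:
        for _ in range(spec.instances_per_sense):
            cues: list[str] = []
            for other in spec.senses:
                p = spec.p_in if other == sense else spec.p_out
                draws = rng.random(spec.planted_words_per_sense)
                cues.extend(w for w, u in zip(planted[other], draws) if u < p)
            draws = rng.random(spec.background_vocab_size)
            noise = [
                w
                for w, u in zip(background, draws)
                if u < spec.background_word_prob
            ]
            cues = [cues[i] for i in rng.permutation(len(cues))]
            noise = [noise[i] for i in rng.permutation(len(noise))]
            present = cues + noise  # innermost first
            inner_left = present[0::2]  # index 0 ends up adjacent to the target
            right = present[1::2]
            left = (
                [_FILLER] * max(0, spec.context_len - len(inner_left))
                + inner_left[::-1]
            )
            right = right + [_FILLER] * max(0, spec.context_len - len(right))
            text = " ".join(left + [spec.target] + right)
            counter += 1
            classes[sense].append(
                Instance(id=f"inst{counter:05d}", target=spec.target, sense=sense, text=text)
            )
    return LabeledCorpus(target=spec.target, classes=classes)


def shuffle_labels(corpus: LabeledCorpus, seed: int) -> LabeledCorpus:
    """Randomly permute sense labels across instances (null-signal control).

    Class sizes are preserved; only the assignment of instances to senses is
    shuffled, destroying any association between context and label.
    """
    rng = np.random.default_rng(seed)
    insts = corpus.instances()
    labels = [inst.sense for inst in insts]
    order = rng.permutation(len(labels))
    shuffled = [labels[i] for i in order]
    classes: dict[str, list[Instance]] = {}
    for inst, sense in zip(insts, shuffled):
        classes.setdefault(sense, []).append(replace(inst, sense=sense))
    return LabeledCorpus(target=corpus.target, classes=classes)
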