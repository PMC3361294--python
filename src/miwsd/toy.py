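"""A tiny worked-example corpus used in the documentation and tests.

Ten instances of an ambiguous pseudo-word ``wx``, five per sense, with two
context words ``wp`` and ``wq``.  ``wp`` occurs in 4 of the 5 first-sense
instances but only 1 second-sense instance (contingency counts a, b, c, d =
4, 1, 1, 4), while ``wq`` is more evenly spread (3, 2, 2, 3).  With N = 10
the MI scores are 1.6 and 1.2 and the M2 scores 4.0 and 1.5, so ``wp`` is
the more discriminative feature under either criterion.
"""

from .corpus import Instance, LabeledCorpus, corpus_from_instances

__all__ = ["toy_corpus", "TOY_SENSE_1", "TOY_SENSE_2"]

TOY_SENSE_1 = "s1"
TOY_SENSE_2 = "s2"

_CONTEXTS = {
    TOY_SENSE_1: [("wp", "wq"), ("wp", "wq"), ("wp",), ("wp",), ("wq",)],
    TOY_SENSE_2: [("wp",), ("wq",), ("wq",), (), ()],
}


def toy_corpus() -> LabeledCorpus:
    """Build the 10-instance, two-sense example corpus."""
    instances = []
    n = 0
    for sense, contexts in _CONTEXTS.items():
        for context in contexts:
            n += 1
            left = context[:1]
            right = context[1:]
            text = " ".join([*left, "wx", *right])
            instances.append(
                Instance(id=f"toy{n:02d}", target="wx", sense=sense, text=text)
            )
    return corpus_from_instances(instances)
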