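"""Default English stoplist.

The disambiguation method removes common function words ("is", "the",
"in", ...) before stemming and windowing.  This fixed, versioned list is
the package default; callers can substitute their own via
:class:`~miwsd.preprocess.PreprocessConfig` or the ``--stoplist`` CLI flag
(one word per line, ``#`` comments allowed).
"""

from pathlib import Path

__all__ = ["DEFAULT_STOPWORDS", "load_stoplist"]

DEFAULT_STOPWORDS: frozenset[str] = frozenset(
    """
    a about above after again against all also am an and any are as at
    be because been before being below between both but by
    can cannot could
    did do does doing down during
    each either few for from further
    had has have having he her here hers herself him himself his how
    i if in into is it its itself
    just me more most my myself
    no nor not now of off on once only onto or other ought our ours
    ourselves out over own
    same she should since so some such
    than that the their theirs them themselves then there these they
    this those through to too
    under until up upon
    very was we were what when where whether which while who whom why
    will with would
    you your yours yourself yourselves
    """.split()
)


def load_stoplist(path: str | Path) -> frozenset[str]:
    """Read a stoplist file: one lowercase word per line, ``#`` comments."""
    words = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        word = line.split("#", 1)[0].strip().lower()
        if word:
            words.append(word)
    return frozenset(words)
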