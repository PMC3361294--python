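"""Shared low-level tokenizer.

Both the corpus validator and the preprocessing pipeline need the same
notion of a token, so it lives here to avoid an import cycle.
"""

import re

_TOKEN_RE = re.compile(r"[0-9A-Za-z]+")


def split_tokens(text: str, lowercase: bool = True) -> list[str]:
    """Split ``text`` on non-alphanumeric boundaries, preserving order.

    Punctuation, parentheses and brackets act purely as separators; the
    tokens inside them are kept.  Pure-digit tokens are kept.  No length
    filtering is applied.
    """
    tokens = _TOKEN_RE.findall(text)
    if lowercase:
        tokens = [t.lower() for t in tokens]
    return tokens
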