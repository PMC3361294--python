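"""Exception hierarchy.

All package-specific failures derive from :class:`MiwsdError` so callers
(and the CLI) can distinguish domain errors from programming errors.
"""


class MiwsdError(Exception):
    """Base class for all miwsd errors."""


class CorpusFormatError(MiwsdError):
    """A corpus file could not be parsed (carries the offending line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(MiwsdError):
    """A domain invariant was violated (bad record, ineligible corpus, ...)."""


class ContextError(MiwsdError):
    """Context extraction failed for a specific instance."""

    def __init__(self, message: str, instance_id: str | None = None):
        self.instance_id = instance_id
        if instance_id is not None:
            message = f"instance {instance_id!r}: {message}"
        super().__init__(message)
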