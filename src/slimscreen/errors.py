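"""Exception hierarchy for slimscreen.

All loader and validation failures derive from :class:`SlimScreenError`
so callers can catch one base class; parse errors carry the offending
line number when known.
"""


class SlimScreenError(ValueError):
    """Base class for all slimscreen errors."""


class ParseError(SlimScreenError):
    """A file could not be parsed; ``line`` is 1-based when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(SlimScreenError):
    """An invariant of a domain type was violated."""


class BindingError(ValidationError):
    """A cross-reference (e.g. hallmark map -> gene sets) failed to resolve."""
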