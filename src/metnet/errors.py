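"""Exception hierarchy shared across the package.

All errors raised on bad user input derive from :class:`MetnetError` so that
callers (and the command-line front end) can distinguish data problems from
programming bugs.
"""


class MetnetError(Exception):
    """Base class for all errors raised on invalid input or state."""


class FormatError(MetnetError):
    """A file could not be parsed (syntax-level problem)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(MetnetError):
    """Parsed data violates a model/network invariant."""


class VertexNotFoundError(MetnetError):
    """A vertex (or metabolite/reaction) id does not exist."""


class UsageError(MetnetError):
    """An operation was called with out-of-range or contradictory options."""
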