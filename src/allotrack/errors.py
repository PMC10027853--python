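"""Exception hierarchy shared across the package.

All parsing and validation failures raise one of these so callers can
distinguish malformed inputs (``FormatError``, ``ParseError``) from
out-of-range parameters (``ValidationError``).
"""


class AllotrackError(Exception):
    """Base class for all package errors."""


class FormatError(AllotrackError):
    """A file does not conform to the expected format (missing column,
    dimension mismatch, unknown dialect)."""


class ParseError(AllotrackError):
    """A value inside an otherwise well-formed file cannot be parsed.

    Carries ``row`` (1-based data-row number) when known.
    """

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)
        self.row = row


class ValidationError(AllotrackError):
    """A parameter or in-memory object violates its contract."""
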