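"""Exception hierarchy."""


class TlsscapeError(Exception):
    """Base class for all package errors."""


class SchemaError(TlsscapeError):
    """A table is missing a mandatory column or has an unusable header."""


class ParseError(TlsscapeError):
    """A row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class ConfigError(TlsscapeError):
    """A definition, spec or run configuration references something unknown."""


class AlignmentError(TlsscapeError):
    """Two tables that must share a patient set do not."""


class UnfittableError(TlsscapeError):
    """A model cannot be fitted from the given outcomes (e.g. zero events)."""


class PlacementError(TlsscapeError):
    """Simulated geometry could not be placed within the retry budget."""
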