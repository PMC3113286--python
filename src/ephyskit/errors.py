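"""Exception hierarchy shared by all modules."""


class EphysError(Exception):
    """Base class for all ephyskit errors."""


class FormatError(EphysError):
    """A file could not be parsed as the expected container format."""


class ParseError(EphysError):
    """A text file has a malformed line.

    Carries the 1-based line (or row) number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConsistencyError(EphysError):
    """A container's fields violate one of its invariants."""


class ParameterError(EphysError):
    """An operation was called with invalid or inconsistent parameters."""
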