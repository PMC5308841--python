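"""Exception hierarchy shared across the package."""


class LatentConnError(Exception):
    """Base class for all package-specific errors."""


class ParseError(LatentConnError):
    """A delimited input file could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class LabelMismatchError(LatentConnError):
    """Node labels of two artifacts do not agree."""

    def __init__(self, message: str, offending: list[str] | None = None):
        self.offending = offending or []
        if self.offending:
            message = f"{message}: {', '.join(map(str, self.offending))}"
        super().__init__(message)


class ArchiveError(LatentConnError):
    """A posterior sample archive is corrupt or version-incompatible."""


class ValidationError(LatentConnError):
    """Invalid in-memory data or configuration."""
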