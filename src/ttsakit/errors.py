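"""Exception hierarchy for ttsakit."""


class TTSaError(Exception):
    """Base class for all ttsakit errors."""


class UsageError(TTSaError):
    """Invalid arguments or configuration (bad dialect, inverted ranges, ...)."""


class ParseError(TTSaError):
    """Malformed input file; message names the offending line."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ValidationError(TTSaError):
    """Input violates a structural invariant (e.g. coordinate outside chromosome)."""


class DegenerateTableError(TTSaError):
    """A 2x2 contingency table has a zero margin; the exact test is undefined."""


class InsufficientDataError(TTSaError):
    """Too few points left after filtering to compute a statistic."""


class PackingError(TTSaError):
    """Synthetic genome too small to place the requested features."""
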