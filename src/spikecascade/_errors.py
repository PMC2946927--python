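"""Exception hierarchy shared across the package."""


class SpikeCascadeError(Exception):
    """Base class for all package errors."""


class ParseError(SpikeCascadeError):
    """Malformed input file; carries the offending (0-based) line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ConfigError(SpikeCascadeError):
    """Invalid configuration or unknown format/option."""


class ParameterError(SpikeCascadeError, ValueError):
    """A numeric parameter outside its valid domain."""


class InsufficientDataError(SpikeCascadeError):
    """Series too short for the requested operation."""


class DegenerateSeriesError(SpikeCascadeError):
    """Zero-variance or otherwise degenerate data where spread is required."""
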