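"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError → 1, ParseError /
ValidationError → 2, InsufficientDataError / DegenerateDataError → 3.
"""


class StillwatchError(Exception):
    """Base class for all package errors."""


class ConfigError(StillwatchError, ValueError):
    """Invalid configuration or arguments."""


class ParseError(StillwatchError, ValueError):
    """Malformed input file; message names the offending line."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(StillwatchError, ValueError):
    """Well-formed input violating a domain invariant."""


class DegenerateFrameError(ValidationError):
    """A landmark frame unusable for the metric (e.g. coincident eye centers)."""


class InsufficientDataError(StillwatchError, RuntimeError):
    """Not enough data to run an analysis (too few participants, pairs, bins)."""


class DegenerateDataError(StillwatchError, RuntimeError):
    """Analysis input with no usable variance or all-missing values."""
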