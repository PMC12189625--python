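"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
ConvergenceError -> 4; anything else propagates as 1.
"""


class NichecastError(Exception):
    """Base class for all package errors."""


class ConfigError(NichecastError):
    """Invalid configuration: unknown scenario, bad threshold, bad grid."""


class DataError(NichecastError):
    """Malformed or insufficient input data."""


class FormatError(DataError):
    """A file does not match its expected schema."""


class GridError(ConfigError):
    """Invalid or incompatible grid definition."""


class AlignmentError(DataError):
    """Two gridded products do not share a compatible grid."""


class ConvergenceError(NichecastError):
    """Optimizer failed to reach the requested tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class EvaluationError(NichecastError):
    """Score-based evaluation is undefined (e.g. an empty class)."""


class SelectionError(NichecastError):
    """Variable selection eliminated every candidate."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class ModelStateError(NichecastError):
    """Operation requires a fitted model."""
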