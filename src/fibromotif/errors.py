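"""Exception types shared across the package."""


class FibromotifError(Exception):
    """Base class for all package-specific errors."""


class InvalidStateError(FibromotifError):
    """A state vector contains non-finite or out-of-domain values."""


class CalibrationError(FibromotifError):
    """A requested operating point cannot be reached within the search bracket."""


class UndefinedMetricError(FibromotifError):
    """A metric is undefined for the given input (distinct from a zero value)."""


class SolverError(FibromotifError):
    """Integration failed; carries the last valid state and time when known."""

    def __init__(self, message, last_state=None, last_time=None):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time


class ConfigError(FibromotifError):
    """A run configuration violates the schema."""
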