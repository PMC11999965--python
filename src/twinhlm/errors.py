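"""Exception types shared across the package."""


class TwinHlmError(Exception):
    """Base class for package errors."""


class DegenerateInputError(TwinHlmError, ValueError):
    """An input with zero total variance (or similar) makes the quantity undefined."""


class OverAdjustmentError(TwinHlmError, ValueError):
    """The measurement-error adjustment drove a variance denominator to <= 0.

    Carries the raw (unadjusted) value so callers can apply a fallback policy.
    """

    def __init__(self, message: str, raw_value: float | None = None):
        super().__init__(message)
        self.raw_value = raw_value


class UnbalancedDataError(TwinHlmError, ValueError):
    """Moment estimators require a balanced design (equal trial counts, 2 twins/family)."""


class IdentifiabilityError(TwinHlmError, ValueError):
    """The requested variance components are not separately identifiable from the data."""


class SchemaError(TwinHlmError, ValueError):
    """A tabular input violates the expected column schema or key constraints."""


class ConvergenceError(TwinHlmError, RuntimeError):
    """An iterative fit failed to converge."""
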