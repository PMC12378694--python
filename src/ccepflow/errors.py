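"""Exception hierarchy shared across the pipeline."""


class CcepflowError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(CcepflowError):
    """A configuration object violates its invariants."""


class InvalidInputError(CcepflowError):
    """An operation received data it cannot process."""


class OutOfBoundsError(InvalidInputError):
    """A coordinate maps outside the sampled volume (with margin)."""


class DegenerateInputError(InvalidInputError):
    """Too few values, or zero variance, where a spread is required."""


class MissingCategoryError(InvalidInputError):
    """A patient lacks edges for one or more connectivity categories."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"no edges for categories: {', '.join(self.missing)}")


class MissingDataError(InvalidInputError):
    """A required clinical field is absent for a patient."""


class CalibrationError(CcepflowError):
    """Amplitude calibration failed to converge; carries last residuals."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class StratificationError(InvalidInputError):
    """A class is too small to stratify the requested split/folds."""


class ConsistencyError(InvalidInputError):
    """Channel labels contradict each other (e.g. SOZ outside resection)."""
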