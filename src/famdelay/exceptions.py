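"""Exception hierarchy shared across the package."""


class FamdelayError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FamdelayError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class ValidationError(FamdelayError, ValueError):
    """Structured input (record, table, config) fails validation."""


class ChoiceLogError(ValidationError):
    """A recorded choice log is incomplete or inconsistent with the
    adjusting-amount schedule.

    Attributes
    ----------
    delay_days : int or None
        Delay block in which the problem was found.
    trial_index : int or None
        1-based trial within the block, when applicable.
    """

    def __init__(self, message, delay_days=None, trial_index=None):
        super().__init__(message)
        self.delay_days = delay_days
        self.trial_index = trial_index


class ReferenceLookupError(FamdelayError, LookupError):
    """A growth-reference table does not cover the requested sex/age."""


class ModelFitError(FamdelayError, RuntimeError):
    """A statistical model cannot be estimated from the given data."""
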