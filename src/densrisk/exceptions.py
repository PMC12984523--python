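"""Exception hierarchy shared across the package."""


class DensriskError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DensriskError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class CohortFormatError(DensriskError, ValueError):
    """A cohort file violates the expected CSV contract."""


class SingularDesignError(DensriskError, ValueError):
    """The regression design matrix is rank deficient."""


class DegenerateComparisonError(DensriskError, ValueError):
    """A paired comparison where every difference is zero."""


class DivergenceError(DensriskError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None) -> None:
        self.epoch = epoch
        super().__init__(message or f"non-finite loss encountered at epoch {epoch}")


class NotFittedError(DensriskError, RuntimeError):
    """An operation requiring a fitted model was called on an unfitted one."""
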