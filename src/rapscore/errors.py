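"""Exception hierarchy shared across the package."""


class RapsError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RapsError):
    """A file or feature schema cannot be resolved (missing column, unknown code)."""


class RowValidationError(RapsError):
    """A single register row failed validation. Carries the row number and reason."""

    def __init__(self, row: int, reason: str):
        self.row = row
        self.reason = reason
        super().__init__(f"row {row}: {reason}")


class ConstraintViolation(RapsError):
    """A scoring-constraint violation (e.g. R1 and R2 present on the same side)."""


class EmptyRegisterError(RapsError):
    """A control register was requested from zero records."""


class UnresolvableStratumError(RapsError):
    """No control stratum could be resolved, even after age pooling."""


class ConfigurationError(RapsError):
    """A simulation or pipeline configuration is internally inconsistent."""
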