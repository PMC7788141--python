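"""Exception types shared across the package."""


class PetqcError(Exception):
    """Base class for all package errors."""


class PresetNotFoundError(PetqcError):
    """Requested camera preset name is not shipped and is not a readable file."""


class PresetValidationError(PetqcError):
    """A preset config failed validation.

    Carries the list of offending fields in ``fields``.
    """

    def __init__(self, fields: list[str]):
        self.fields = list(fields)
        super().__init__(
            "invalid preset configuration; offending fields: " + ", ".join(self.fields)
        )


class FitError(PetqcError):
    """Nonlinear fit failed to converge across all starts.

    ``best_rmse`` carries the residual of the best attempt, when available.
    """

    def __init__(self, message: str, best_rmse: float | None = None):
        self.best_rmse = best_rmse
        super().__init__(message)


class DomainError(PetqcError):
    """Input outside the mathematical domain of an operation."""


class UnsupportedPhantomError(PetqcError):
    """Operation requires a different phantom kind."""


class SchemaError(PetqcError):
    """List-mode container does not match the expected schema."""


class InsufficientDataError(PetqcError):
    """Too few events to produce a reliable estimate."""


class NoPeakError(PetqcError):
    """A rate series is monotone and has no interior maximum.

    ``direction`` is ``"increasing"`` or ``"decreasing"``.
    """

    def __init__(self, direction: str):
        self.direction = direction
        super().__init__(f"series is monotone {direction}; no interior peak")
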