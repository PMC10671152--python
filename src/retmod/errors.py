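"""Exception hierarchy for retmod.

Every error raised by the library derives from :class:`RetmodError`, split
into configuration/validation failures (exit code 2 at the CLI) and numerical
failures (exit code 3).
"""


class RetmodError(Exception):
    """Base class for all retmod errors."""


class ValidationError(RetmodError):
    """Invalid inputs, configuration, or malformed tables."""


class InvalidConditionsError(ValidationError):
    """Run conditions violate a physical invariant (flow <= 0, x outside [0, 1], ...)."""


class InvalidConfigurationError(ValidationError):
    """Column/instrument configuration violates an invariant."""


class InvalidDesignError(ValidationError):
    """Design level counts are outside what the calibration supports."""


class IncompleteDesignError(ValidationError):
    """A corner-run table is missing one or more design cells."""

    def __init__(self, message, missing_cells=()):
        super().__init__(message)
        self.missing_cells = list(missing_cells)


class IncompleteEvidenceError(ValidationError):
    """Peak tracking is missing a required mixture injection."""


class SchemaError(ValidationError):
    """A CSV/JSON artifact does not match its documented schema."""


class NumericalError(RetmodError):
    """Numerical failures (non-convergence, fit failure)."""


class SolverError(NumericalError):
    """The gradient migration solver failed to converge."""


class UnidentifiableParametersError(NumericalError):
    """Two-run data cannot identify (log kw, S): solute unretained or
    eluting inside the dwell/initial hold in both runs."""


class FitFailureError(NumericalError):
    """Coefficient fit residual exceeded tolerance after multi-start."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class GenerationError(RetmodError):
    """Synthetic truth generation could not satisfy its invariants."""
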