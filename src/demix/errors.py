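"""Exception hierarchy.

Everything raised on purpose derives from :class:`DemixError` so callers can
catch the package's own failures separately from programming errors.
"""


class DemixError(Exception):
    """Base class for all demix errors."""


class InvalidInputError(DemixError, ValueError):
    """Non-finite or otherwise malformed numeric input."""


class DomainError(DemixError, ValueError):
    """Input outside the mathematical domain of an operation."""


class ShapeError(DemixError, ValueError):
    """Mismatched vector/matrix dimensions."""


class CompositionError(DemixError, ValueError):
    """Volume fractions violating the unit-sum (volume conservation) constraint."""


class ConditioningError(DemixError, RuntimeError):
    """System matrix too ill-conditioned to invert reliably."""


class InsufficientDataError(DemixError, ValueError):
    """Too few data points for the requested fit."""


class DegenerateDesignError(DemixError, ValueError):
    """Regression design with no usable variance."""


class ConfigurationError(DemixError, ValueError):
    """Missing or inconsistent configuration (units, stock concentrations, ...)."""


class OptimizationError(DemixError, RuntimeError):
    """Optimizer failed to produce a usable result.

    Carries the best incumbent found (if any) in :attr:`incumbent`.
    """

    def __init__(self, message, incumbent=None):
        super().__init__(message)
        self.incumbent = incumbent


class ParseError(DemixError, ValueError):
    """Malformed input table row; message names the offending row."""


class DegenerateGeometryWarning(UserWarning):
    """Collinear optimization-path vectors; fit reduced to fewer extras."""
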