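"""Exception hierarchy.

All package errors derive from :class:`MlcQrarError` so callers can catch
one base class at pipeline boundaries.
"""


class MlcQrarError(Exception):
    """Base class for all package errors."""


class ParseError(MlcQrarError):
    """A cell in a delimited input could not be parsed as a number."""


class SchemaError(MlcQrarError):
    """A column required by the schema is absent from the input."""


class ValidationError(MlcQrarError):
    """A table or record violates a domain invariant."""


class MissingFieldError(MlcQrarError):
    """An operation consumed a column containing missing values."""


class BelowCmcError(MlcQrarError):
    """Total surfactant below the critical micellization concentration."""


class InvalidFitError(MlcQrarError):
    """Reciprocal-space regression yielded a non-positive intercept."""


class InsufficientDataError(MlcQrarError):
    """Too few observations for the requested fit."""


class DegenerateDesignError(MlcQrarError):
    """Design has zero variance in a required direction."""


class SingularDesignError(MlcQrarError):
    """Design matrix is rank deficient."""


class LeverageOneError(MlcQrarError):
    """An observation has leverage 1; leave-one-out is undefined."""


class DegenerateModelError(MlcQrarError):
    """Residual standard deviation is zero; standardization undefined."""


class DegenerateColumnError(MlcQrarError):
    """A predictor column has zero sample variance."""


class ConfigError(MlcQrarError):
    """A simulation or pipeline configuration is infeasible."""
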