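"""Exception hierarchy for seabird_cascade.

Errors are grouped by where in the analysis they arise: invalid simulation
or model parameters, malformed input tables, sampler pathologies, and
geographic extraction failures.
"""


class SeabirdCascadeError(Exception):
    """Base class for all package errors."""


class ParameterError(SeabirdCascadeError, ValueError):
    """A simulation or model parameter violates its domain constraints."""


class SchemaError(SeabirdCascadeError, ValueError):
    """An input table is missing required columns or has malformed values."""


class DegenerateDesignError(SeabirdCascadeError, ValueError):
    """A covariate has zero variance, making the design unidentifiable."""


class InsufficientChainsError(SeabirdCascadeError, ValueError):
    """Fewer than two MCMC chains; convergence diagnostics undefined."""


class InsufficientDrawsError(SeabirdCascadeError, ValueError):
    """Too few posterior draws for the requested diagnostic."""


class SamplerDiagnosticsError(SeabirdCascadeError, RuntimeError):
    """Sampler health check failed (e.g. Metropolis acceptance below limit).

    Carries a ``report`` dict describing the failure.
    """

    def __init__(self, message: str, report: dict | None = None):
        super().__init__(message)
        self.report = report or {}


class EmptyExtractionError(SeabirdCascadeError, ValueError):
    """A foraging disc does not intersect the prey-field grid."""


class UnitMismatchError(SeabirdCascadeError, ValueError):
    """Metadata indicates inconsistent units between two quantities."""


class ConfigurationError(SeabirdCascadeError, ValueError):
    """Species profile or constants configuration is incomplete."""


class UndefinedRatioError(SeabirdCascadeError, ZeroDivisionError):
    """Fold change requested against a zero current total."""


class JoinError(SeabirdCascadeError, ValueError):
    """Island sets of two tables do not match where they must."""
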