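"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`FruitcastError` so that callers
(and the CLI) can catch pipeline problems without masking programming
errors.
"""


class FruitcastError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FruitcastError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class CoverageError(FruitcastError):
    """A query falls outside the span of the temperature record."""


class InsufficientDataError(FruitcastError):
    """Too few observations to perform a fit or split."""


class DegenerateDataError(FruitcastError):
    """Data has no variance (or is otherwise degenerate) where variance is required."""


class SchemaError(FruitcastError):
    """Feature/column layout does not match what the operation expects."""


class GateError(FruitcastError):
    """A fruit failed a quality-control gate and cannot be used downstream."""


class SolverError(FruitcastError):
    """A linear system could not be solved (e.g. singular at lambda = 0)."""


class ConfigError(FruitcastError):
    """A pipeline configuration is invalid."""
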