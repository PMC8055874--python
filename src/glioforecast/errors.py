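"""Exception hierarchy used across the package."""


class GlioForecastError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(GlioForecastError, ValueError):
    """A parameter value violates its physical or numerical constraints."""


class InvariantViolationError(GlioForecastError, ValueError):
    """A domain object violates one of its declared invariants."""


class GridMismatchError(GlioForecastError, ValueError):
    """Two volumes that must share a grid do not."""


class ManifestError(GlioForecastError, ValueError):
    """A patient manifest is malformed or references missing data."""


class SolverError(GlioForecastError, RuntimeError):
    """A linear or nonlinear solve failed to reach its tolerance."""


class InstabilityError(SolverError):
    """The explicit time integration produced non-finite values."""


class InsufficientDataError(GlioForecastError, ValueError):
    """A dataset lacks the visits required by the requested scenario."""


class UndefinedMetricError(GlioForecastError, ValueError):
    """A metric is undefined for the given input (e.g. zero variance)."""
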