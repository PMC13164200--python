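"""Exception hierarchy for the forecasting pipeline.

Every stage raises a subclass of :class:`AAAForecastError` so callers (and the
CLI) can distinguish user/data problems from genuine bugs.
"""


class AAAForecastError(Exception):
    """Base class for all package errors."""


class MeshFormatError(AAAForecastError):
    """A mesh file could not be read or parsed."""


class MeshValidationError(AAAForecastError):
    """A mesh violates a geometric invariant (e.g. not watertight)."""

    def __init__(self, message: str, open_edges: int | None = None):
        super().__init__(message)
        self.open_edges = open_edges


class InsufficientDataError(AAAForecastError):
    """Fewer scans than the pipeline requires."""


class CoverageError(AAAForecastError):
    """An axial level produced no cross-section."""

    def __init__(self, message: str, level: int | None = None):
        super().__init__(message)
        self.level = level


class IdentifiabilityError(AAAForecastError):
    """A smoothing/fitting basis has more parameters than data points."""


class ExtrapolationError(AAAForecastError):
    """A requested grid lies outside the available axial extent."""


class EmptySliceError(AAAForecastError):
    """A slicing plane does not intersect the surface."""


class TopologyError(AAAForecastError):
    """Plane-intersection segments could not be chained into closed loops."""


class GeometryError(AAAForecastError):
    """Degenerate geometry (zero perimeter/area contour)."""


class ParameterizationError(AAAForecastError):
    """Cylindrical mapping precondition violated (center outside contour)."""


class DegenerateSamplesError(AAAForecastError):
    """Angular samples collapse to a single angle."""


class LatticeError(AAAForecastError):
    """Grid and centerline lattices are inconsistent."""


class RegimeError(AAAForecastError):
    """A fitting regime's scan-count precondition is violated."""


class ConvergenceError(AAAForecastError):
    """Likelihood optimisation failed after restarts.

    Carries the best fit found so far in ``best_fit``.
    """

    def __init__(self, message: str, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class ConfigError(AAAForecastError):
    """Invalid configuration value."""
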