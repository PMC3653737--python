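"""Error hierarchy for structure-set comparison.

All package-specific failures derive from :class:`ContourBenchError` so
callers (and the CLI) can distinguish domain errors from programming bugs.
"""


class ContourBenchError(Exception):
    """Base class for all contourbench domain errors."""


class DegenerateContourError(ContourBenchError):
    """Fewer than 3 distinct vertices after normalization."""


class InvalidGeometryError(ContourBenchError):
    """Self-intersecting or otherwise non-simple polygon."""


class EmptyStructureError(ContourBenchError):
    """Operation requires at least one contour."""


class SliceMismatchError(ContourBenchError):
    """Two per-slice polygon sets are not on the same axial plane."""


class GridMismatchError(ContourBenchError):
    """Structures live on incompatible slice grids."""


class ZeroAreaError(ContourBenchError):
    """Polygon area is zero (collinear vertices)."""


class OutOfBoundsError(ContourBenchError):
    """Polygon does not fit inside a raster grid."""


class InvalidReferenceError(ContourBenchError):
    """Reference volume is non-positive where a ratio requires it."""


class InconsistentVolumesError(ContourBenchError):
    """Intersection volume exceeds one of the intersected volumes."""


class InsufficientObserversError(ContourBenchError):
    """Fewer observers than the statistic requires."""


class MissingStructureError(ContourBenchError):
    """Requested structure role is absent from a structure set."""


class InsufficientFiducialsError(ContourBenchError):
    """Fewer than 2 matched fiducial pairs, or no fiducials at all."""


class AmbiguousAlignmentError(ContourBenchError):
    """Fiducial residual too large for a pure translation/inversion model."""


class ConfigError(ContourBenchError):
    """Invalid synthetic-cohort or run configuration."""


class GenerationError(ContourBenchError):
    """Synthetic perturbation failed to produce a simple polygon."""
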