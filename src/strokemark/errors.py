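"""Exception hierarchy shared across the pipeline."""


class StrokemarkError(Exception):
    """Base class for all package-specific errors."""


class DimensionalityError(StrokemarkError, ValueError):
    """Raised for volumes that are not 3D (or 4D where 4D is not allowed)."""


class GridMismatchError(StrokemarkError, ValueError):
    """Raised when two gridded objects disagree in shape or world transform."""


class GeometryError(StrokemarkError, ValueError):
    """Raised for degenerate voxel geometry (e.g. singular world transform)."""


class EmptyLesionError(StrokemarkError, ValueError):
    """Raised when an operation requires a non-empty lesion mask."""


class EmptyTractError(StrokemarkError, ValueError):
    """Raised when a tract mask is empty after resampling."""


class DegenerateGeometryError(StrokemarkError, ValueError):
    """Raised when a lesion is too degenerate for a shape descriptor
    (e.g. coplanar voxels for a convex hull)."""


class DomainError(StrokemarkError, ValueError):
    """Raised when a scalar input is outside the mathematical domain
    of a formula (e.g. non-positive volume for sphericity)."""


class UndefinedFeatureError(StrokemarkError, ValueError):
    """Raised when a texture feature is undefined (no valid pixel pairs)."""


class DegenerateLabelsError(StrokemarkError, ValueError):
    """Raised when outcome labels contain a single class where two are needed."""
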