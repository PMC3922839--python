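"""Exception types raised across the package."""


class OctovarioError(Exception):
    """Base class for all package-specific errors."""


class VolumeIOError(OctovarioError):
    """A volume file could not be read or written."""


class DimensionalityError(OctovarioError):
    """Input data is not a 3D scalar volume."""


class SpacingError(OctovarioError):
    """Voxel spacing is missing, non-positive, or anisotropic."""


class ShapeError(OctovarioError):
    """Array shapes are incompatible (mask/volume mismatch, non-cube input...)."""


class SeedError(OctovarioError):
    """A region-growing seed is out of bounds or outside the threshold range."""


class ParameterError(OctovarioError):
    """An operation parameter is out of its valid range."""


class InsufficientDataError(OctovarioError):
    """Too few observations to compute the requested quantity."""


class AlignmentError(OctovarioError):
    """Variogram distance grids do not match and cannot be combined."""


class GeometryError(OctovarioError):
    """A synthetic lesion or structure does not intersect the lung region."""


class EmptyMaskError(OctovarioError):
    """A masked volume contains no foreground voxels."""


class FitError(OctovarioError):
    """A least-squares fit failed to converge."""
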