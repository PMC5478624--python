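"""Exception hierarchy for the seedbed3d pipeline."""


class Seedbed3DError(Exception):
    """Base class for all package-specific errors."""


class InvalidSampleError(Seedbed3DError):
    """A depth sample is non-positive or otherwise unusable."""


class BoundsError(Seedbed3DError):
    """A pixel coordinate falls outside the image."""


class BehindCameraError(Seedbed3DError):
    """A 3D point with Z <= 0 cannot be projected."""


class EmptyCloudError(Seedbed3DError):
    """A depth frame contains no valid samples."""


class InsufficientExtentError(Seedbed3DError):
    """A point cloud is too degenerate to rasterize (single point / collinear)."""


class DegenerateFitError(Seedbed3DError):
    """A least-squares surface fit is rank deficient."""


class ParameterError(Seedbed3DError):
    """A configuration parameter is outside its documented range."""


class EmptyInputError(Seedbed3DError):
    """An operation received a field with no valid cells."""


class UndefinedStatisticError(Seedbed3DError):
    """A statistic is undefined for the given input (e.g. Sq = 0)."""


class InputError(Seedbed3DError):
    """Mismatched or malformed inputs (shapes, lengths, ids)."""


class GeometryError(Seedbed3DError):
    """A scene/camera configuration is physically impossible."""
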