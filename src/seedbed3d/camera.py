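"""Pinhole camera geometry for nadir-mounted depth sensors.

A structured-light depth camera reports, for every pixel ``(x', y')``, the
range ``depth(x', y')`` along the optical axis in millimetres (0 marks a
hole).  With focal lengths ``fx_d, fy_d`` (pixels) and principal point
``(cx, cy)`` the metric camera-frame coordinates of the surface point seen
by that pixel are

    X = (x' - cx) * depth / fx_d
    Y = (y' - cy) * depth / fy_d
    Z = depth

This module converts between pixels and points and rasterizes nadir-view
point clouds into regular metric height grids, the domain on which all
surface statistics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    BehindCameraError,
    BoundsError,
    EmptyCloudError,
    InsufficientExtentError,
    InvalidSampleError,
    ParameterError,
)
from .surface import HeightField

#: Typical structured-light (Kinect-v1 class) depth-camera calibration, used
#: when a frame carries no calibration of its own.
DEFAULT_FX = 585.6
DEFAULT_FY = 585.6
DEFAULT_CX = 316.0
DEFAULT_CY = 247.6
DEFAULT_WIDTH = 640
DEFAULT_HEIGHT = 480
DEFAULT_CAMERA_HEIGHT_MM = 800.0


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics of the depth camera (all units: pixels)."""

    fx_d: float = DEFAULT_FX
    fy_d: float = DEFAULT_FY
    cx: float = DEFAULT_CX
    cy: float = DEFAULT_CY
    width: int = DEFAULT_WIDTH
    height: int = DEFAULT_HEIGHT

    def __post_init__(self) -> None:
        if self.fx_d <= 0 or self.fy_d <= 0:
            raise ParameterError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ParameterError("principal point must lie inside the image")

    @property
    def ground_sample_distance(self) -> float:
        """Pixel footprint on the ground (mm/px) at the nominal camera height."""
        return DEFAULT_CAMERA_HEIGHT_MM / self.fx_d


@dataclass
class DepthImage:
    """A single raw depth frame: range per pixel in mm, 0 = hole."""

    values: np.ndarray  # (height, width) array, mm
    intrinsics: CameraIntrinsics = field(default_factory=CameraIntrinsics)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("depth image must be a 2D array")
        if np.any(self.values < 0):
            raise InvalidSampleError("depth values must be >= 0")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of pixels carrying a real range sample."""
        return self.values > 0


@dataclass
class PointCloud:
    """Metric camera-frame points (X, Y, Z) in mm; Z is range, always > 0."""

    points: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.points.size and not np.all(np.isfinite(self.points)):
            raise InvalidSampleError("point cloud contains non-finite coordinates")
        if self.points.size and np.any(self.points[:, 2] <= 0):
            raise InvalidSampleError("point cloud contains points with Z <= 0")

    def __len__(self) -> int:
        return self.points.shape[0]


def unproject_pixel(
    x_prime: float, y_prime: float, depth: float, intrinsics: CameraIntrinsics
) -> tuple[float, float, float]:
    """Back-project one pixel with its depth into a metric 3D point (mm)."""
    if depth <= 0:
        raise InvalidSampleError(f"depth must be positive, got {depth}")
    if not (0 <= x_prime < intrinsics.width and 0 <= y_prime < intrinsics.height):
        raise BoundsError(
            f"pixel ({x_prime}, {y_prime}) outside "
            f"{intrinsics.width}x{intrinsics.height} image"
        )
    x = (x_prime - intrinsics.cx) * depth / intrinsics.fx_d
    y = (y_prime - intrinsics.cy) * depth / intrinsics.fy_d
    return (x, y, float(depth))


def project_point(
    point: tuple[float, float, float], intrinsics: CameraIntrinsics
) -> tuple[float, float, float]:
    """Project a metric camera-frame point back to (x', y', depth).

    Algebraic inverse of :func:`unproject_pixel`; the returned pixel
    coordinates are continuous (not rounded).
    """
    x, y, z = point
    if z <= 0:
        raise BehindCameraError(f"cannot project point with Z = {z} <= 0")
    x_prime = x * intrinsics.fx_d / z + intrinsics.cx
    y_prime = y * intrinsics.fy_d / z + intrinsics.cy
    return (x_prime, y_prime, float(z))


def depth_to_point_cloud(image: DepthImage) -> PointCloud:
    """Back-project every valid pixel of a depth frame; holes are skipped."""
    mask = image.valid_mask
    if not mask.any():
        raise EmptyCloudError("depth image contains no valid samples")
    rows, cols = np.nonzero(mask)
    depth = image.values[rows, cols]
    intr = image.intrinsics
    x = (cols - intr.cx) * depth / intr.fx_d
    y = (rows - intr.cy) * depth / intr.fy_d
    return PointCloud(np.column_stack([x, y, depth]))


def point_cloud_to_heightfield(
    cloud: PointCloud,
    camera_height_mm: float = DEFAULT_CAMERA_HEIGHT_MM,
    grid_pitch_mm: float | None = None,
) -> HeightField:
    """Rasterize a nadir-view cloud into a regular metric height grid.

    Heights are measured upward from the camera's ground reference,
    ``h = camera_height - Z``, so protruding clods are positive bumps.
    Each grid cell takes the mean height of the points falling inside it;
    cells supported by no point are marked invalid.

    Parameters
    ----------
    cloud
        Camera-frame points in mm, Z = range.
    camera_height_mm
        Sensor height above the reference ground plane.
    grid_pitch_mm
        Cell size; defaults to the ground-sample distance at the nominal
        camera height (nearly lossless for nadir geometry).
    """
    if len(cloud) == 0:
        raise EmptyCloudError("cannot rasterize an empty cloud")
    if grid_pitch_mm is None:
        grid_pitch_mm = camera_height_mm / DEFAULT_FX
    if grid_pitch_mm <= 0:
        raise ParameterError("grid pitch must be positive")

    pts = cloud.points
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    h = camera_height_mm - z

    x0, y0 = x.min(), y.min()
    ix = np.floor((x - x0) / grid_pitch_mm).astype(np.intp)
    iy = np.floor((y - y0) / grid_pitch_mm).astype(np.intp)
    ncols = int(ix.max()) + 1
    nrows = int(iy.max()) + 1
    if nrows < 2 or ncols < 2:
        raise InsufficientExtentError(
            "cloud extent smaller than one grid cell in some direction"
        )

    flat = iy * ncols + ix
    counts = np.bincount(flat, minlength=nrows * ncols)
    sums = np.bincount(flat, weights=h, minlength=nrows * ncols)
    valid = counts > 0
    mean = np.zeros(nrows * ncols)
    mean[valid] = sums[valid] / counts[valid]

    return HeightField(
        z=mean.reshape(nrows, ncols),
        pitch_x=grid_pitch_mm,
        pitch_y=grid_pitch_mm,
        valid=valid.reshape(nrows, ncols),
    )
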