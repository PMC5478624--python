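"""Height-field surface model: form removal and basal/block decomposition.

The reconstructed seedbed surface G(r) is modelled as the sum of a
low-frequency basal ground form and a residual of protruding soil blocks,

    G(r) = G(r)_basal + G(r)_block.

The basal component is estimated with a mask-aware Gaussian low-pass filter
whose scale is a fraction of the image width (default 0.05, i.e. sigma = 32
px on a 640-px frame); the block residual is the exact cell-wise difference,
so the decomposition reconstructs the input identically.

Before any texture statistics are computed, the large-scale form (camera
tilt, field slope) is removed by subtracting a least-squares reference
plane — the areal-texture analogue of the ISO form (F-) operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError

from .errors import (
    DegenerateFitError,
    EmptyInputError,
    ParameterError,
)

#: Basal-filter scale as a fraction of image width.
DEFAULT_SIGMA_FRAC = 0.05


@dataclass
class HeightField:
    """A regular metric grid of surface heights z(x, y).

    Attributes
    ----------
    z : (rows, cols) array
        Heights in mm. Values on invalid cells are ignored everywhere.
    pitch_x, pitch_y : float
        Grid spacing in mm along columns (x) and rows (y).
    valid : (rows, cols) bool array
        Cells supported by data; defaults to all-valid.
    """

    z: np.ndarray
    pitch_x: float = 1.0
    pitch_y: float = 1.0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2:
            raise ParameterError("height field must be a 2D array")
        if self.pitch_x <= 0 or self.pitch_y <= 0:
            raise ParameterError("grid pitch must be positive")
        if self.valid is None:
            self.valid = np.ones(self.z.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.z.shape:
                raise ParameterError("validity mask shape mismatch")
        if not np.all(np.isfinite(self.z[self.valid])):
            raise ParameterError("heights on valid cells must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape

    @property
    def cell_area(self) -> float:
        """Area of one grid cell, mm^2."""
        return self.pitch_x * self.pitch_y

    @property
    def area(self) -> float:
        """Total valid evaluation area A, mm^2."""
        return float(self.valid.sum()) * self.cell_area

    def valid_values(self) -> np.ndarray:
        """1D array of heights on valid cells."""
        return self.z[self.valid]

    def cell_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Metric (x, y) coordinates of every cell centre, mm."""
        rows, cols = self.shape
        x = (np.arange(cols) + 0.5) * self.pitch_x
        y = (np.arange(rows) + 0.5) * self.pitch_y
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class ReferencePlane:
    """Least-squares reference plane z = a*x + b*y + c (x, y, z in mm)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in (self.a, self.b, self.c)):
            raise DegenerateFitError("reference plane has non-finite coefficients")

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.a * x + self.b * y + self.c


@dataclass
class SurfaceDecomposition:
    """Basal ground form plus block residual; reconstructs the input exactly."""

    basal: HeightField
    block: HeightField
    sigma_frac: float


def fit_reference_plane(field: HeightField) -> ReferencePlane:
    """Fit the least-squares plane to the valid cells of a height field."""
    xx, yy = field.cell_coordinates()
    m = field.valid
    if m.sum() < 3:
        raise DegenerateFitError("need at least 3 valid cells to fit a plane")
    A = np.column_stack([xx[m], yy[m], np.ones(int(m.sum()))])
    coeffs, _, rank, _ = np.linalg.lstsq(A, field.z[m], rcond=None)
    if rank < 3:
        raise DegenerateFitError("valid cells are collinear; plane fit is degenerate")
    return ReferencePlane(*map(float, coeffs))


def detrend(field: HeightField, plane: ReferencePlane | None = None) -> HeightField:
    """Subtract a reference plane (fitted to the field itself by default)."""
    if plane is None:
        plane = fit_reference_plane(field)
    xx, yy = field.cell_coordinates()
    return replace(field, z=field.z - plane.evaluate(xx, yy), valid=field.valid.copy())


def _masked_gaussian(values: np.ndarray, mask: np.ndarray, sigma_px: float) -> np.ndarray:
    """Normalized (mask-aware) Gaussian convolution with reflect borders."""
    v = np.where(mask, values, 0.0)
    num = ndimage.gaussian_filter(v, sigma=sigma_px, mode="reflect")
    den = ndimage.gaussian_filter(mask.astype(float), sigma=sigma_px, mode="reflect")
    out = np.zeros_like(num)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    return out


def gaussian_lowpass(
    field: HeightField, sigma_frac: float = DEFAULT_SIGMA_FRAC
) -> HeightField:
    """Estimate the basal ground form by Gaussian low-pass filtering.

    ``sigma_frac`` is dimensionless: the filter sigma in pixels is
    ``sigma_frac * number of columns``. Invalid cells are excluded through
    normalized convolution, so holes neither bleed zeros into the estimate
    nor darken it near borders.
    """
    if not 0 < sigma_frac < 1:
        raise ParameterError("sigma_frac must lie in (0, 1)")
    if not field.valid.any():
        raise EmptyInputError("height field has no valid cells")
    sigma_px = sigma_frac * field.shape[1]
    smoothed = _masked_gaussian(field.z, field.valid, sigma_px)
    return replace(field, z=smoothed, valid=field.valid.copy())


def decompose_surface(
    field: HeightField, sigma_frac: float = DEFAULT_SIGMA_FRAC
) -> SurfaceDecomposition:
    """Split a surface into basal form and block residual.

    The residual is defined as ``input - basal`` cell-wise, so
    ``basal + block`` reconstructs the input exactly on valid cells.
    """
    basal = gaussian_lowpass(field, sigma_frac)
    block = replace(field, z=field.z - basal.z, valid=field.valid.copy())
    return SurfaceDecomposition(basal=basal, block=block, sigma_frac=sigma_frac)


def triangulate(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Delaunay-triangulate a point cloud over its (X, Y) footprint.

    Returns ``(vertices, faces)`` where vertices are the input points (every
    input point is a mesh vertex) and faces index triangles. The
    triangulation is planar in (X, Y) and lifted to Z, which is the natural
    surface mesh for a nadir-viewed single-valued terrain.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 3:
        raise DegenerateFitError("need at least 3 points to triangulate")
    try:
        tri = Delaunay(pts[:, :2])
    except QhullError as exc:
        raise DegenerateFitError(f"degenerate (collinear?) input: {exc}") from exc
    if tri.simplices.size == 0:
        raise DegenerateFitError("triangulation produced no triangles")
    return pts, tri.simplices
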