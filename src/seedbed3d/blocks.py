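"""Soil-clod extraction and measurement from the block residual.

After the basal/block decomposition, the residual surface carries the
protruding soil aggregates ("clods") as positive bumps. This module turns
that residual into a labelled clod inventory: optional blob-enhancing
Laplacian-of-Gaussian response, thresholding into a binary clod mask,
8-connected component labelling with a minimum-area speckle filter, and
per-clod metric measurement.

Clods are binned by area-equivalent diameter into the standard tilth
size classes (<5, 5-15, 15-50, 50-80, 80-120, >120 mm), the classes used to
define the 10 seedbed grades.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import remove_small_objects

from .errors import EmptyInputError, InputError, ParameterError
from .surface import DEFAULT_SIGMA_FRAC, HeightField

#: Tilth size-class edges in mm; the top class is open-ended.
SIZE_CLASS_EDGES = (0.0, 5.0, 15.0, 50.0, 80.0, 120.0, np.inf)
SIZE_CLASS_LABELS = ("<5", "5-15", "15-50", "50-80", "80-120", ">120")

#: Minimum clod footprint in cells; suppresses single-pixel depth speckles.
DEFAULT_MIN_AREA_CELLS = 4


@dataclass(frozen=True)
class FilterSpec:
    """Configuration of the block binarization step.

    ``threshold_method`` is ``"otsu"`` (threshold from the residual height
    histogram; robust to sensor noise), ``"triangle"`` (histogram triangle
    rule; recovers thin clod rims better on low-noise residuals but chases
    speckle on noisy frames), or ``"fixed"`` (``threshold_value`` in mm).
    """

    sigma_frac: float = DEFAULT_SIGMA_FRAC
    threshold_method: str = "otsu"
    threshold_value: float = 0.0
    min_area_cells: int = DEFAULT_MIN_AREA_CELLS

    def __post_init__(self) -> None:
        if self.sigma_frac <= 0:
            raise ParameterError("sigma_frac must be positive")
        if self.threshold_method not in ("otsu", "triangle", "fixed"):
            raise ParameterError("threshold_method must be 'otsu', 'triangle' or 'fixed'")
        if self.threshold_method == "fixed" and self.threshold_value < 0:
            raise ParameterError("fixed threshold must be >= 0")


@dataclass(frozen=True)
class BlockRecord:
    """One segmented soil clod with metric measurements."""

    label: int
    area: float  # mm^2
    length: float  # major-axis extent, mm
    width: float  # minor-axis extent, mm
    height: float  # max residual height, mm
    equivalent_diameter: float  # 2*sqrt(area/pi), mm
    centroid: tuple[float, float]  # (x, y), mm

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ParameterError("clod area must be positive")
        if not self.length >= self.width > 0:
            raise ParameterError("clod extents must satisfy length >= width > 0")


@dataclass
class SizeDistribution:
    """Count fractions of a clod inventory per tilth size class."""

    fractions: np.ndarray  # len 6, sums to 1 when n_blocks > 0
    n_blocks: int
    bin_edges: tuple[float, ...] = SIZE_CLASS_EDGES

    @property
    def is_empty(self) -> bool:
        return self.n_blocks == 0


def log_filter(field: HeightField, sigma_frac: float = DEFAULT_SIGMA_FRAC) -> np.ndarray:
    """Laplacian-of-Gaussian blob response of a height field.

    Returns the negated LoG so that bright bumps (clods) give positive
    extrema; the response is identically zero on constant fields.
    """
    if sigma_frac <= 0:
        raise ParameterError("sigma_frac must be positive")
    sigma_px = sigma_frac * field.shape[1]
    # centre first: the truncated derivative kernel is not exactly zero-sum,
    # so a raw constant offset would leak into the response
    z0 = field.z - field.valid_values().mean()
    return -ndimage.gaussian_laplace(z0, sigma=sigma_px, mode="reflect")


def binarize_blocks(residual: HeightField, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Threshold the block residual into a binary clod mask.

    Cells above the threshold are clod (1), everything else basal (0);
    invalid cells are never clod.
    """
    values = residual.valid_values()
    if values.size == 0:
        raise EmptyInputError("residual has no valid cells")
    if spec.threshold_method == "fixed":
        thr = spec.threshold_value
    elif np.ptp(values) == 0:
        thr = np.inf  # degenerate single-valued residual: nothing protrudes
    elif spec.threshold_method == "otsu":
        thr = threshold_otsu(values)
    else:
        thr = threshold_triangle(values)
    return (residual.z > thr) & residual.valid


def label_blocks(
    mask: np.ndarray, min_area_cells: int = DEFAULT_MIN_AREA_CELLS
) -> tuple[np.ndarray, int]:
    """8-connected component labelling with a minimum-area filter.

    Returns the labelled grid (0 = background, 1..n = clods) and n.
    """
    mask = np.asarray(mask, dtype=bool)
    if min_area_cells > 1:
        mask = remove_small_objects(mask, max_size=min_area_cells - 1, connectivity=2)
    labels, n = sk_label(mask, connectivity=2, return_num=True)
    return labels, n


def measure_blocks(labels: np.ndarray, residual: HeightField) -> list[BlockRecord]:
    """Measure every labelled clod on the residual height field.

    Area is footprint cell count times cell area; height is the maximum
    residual height inside the clod; length/width are the major/minor axis
    lengths of the best-fit ellipse (falling back to a one-cell extent for
    degenerate regions); the equivalent diameter is that of the equal-area
    circle.
    """
    if labels.shape != residual.shape:
        raise InputError("label grid and residual field shapes differ")
    if residual.pitch_x != residual.pitch_y:
        raise InputError("clod measurement requires isotropic grid pitch")
    pitch = residual.pitch_x
    records: list[BlockRecord] = []
    for rp in regionprops(labels, intensity_image=residual.z):
        area = rp.area * residual.cell_area
        # regionprops axes are in cells; degenerate (thin) regions can
        # report a zero minor axis
        length = max(rp.axis_major_length, 1.0) * pitch
        width = max(rp.axis_minor_length, 1.0) * pitch
        cy, cx = rp.centroid
        records.append(
            BlockRecord(
                label=int(rp.label),
                area=float(area),
                length=float(max(length, width)),
                width=float(min(length, width)),
                height=float(rp.intensity_max),
                equivalent_diameter=float(2.0 * np.sqrt(area / np.pi)),
                centroid=((cx + 0.5) * pitch, (cy + 0.5) * pitch),
            )
        )
    return records


def size_distribution(blocks: list[BlockRecord]) -> SizeDistribution:
    """Bin a clod inventory by equivalent diameter into the tilth classes.

    Classes are half-open ``[low, high)``: a 5 mm clod counts as 5-15 mm.
    """
    if not blocks:
        return SizeDistribution(fractions=np.zeros(len(SIZE_CLASS_LABELS)), n_blocks=0)
    d = np.array([b.equivalent_diameter for b in blocks])
    counts, _ = np.histogram(d, bins=np.array(SIZE_CLASS_EDGES))
    return SizeDistribution(fractions=counts / len(d), n_blocks=len(d))


def blocks_to_frame(blocks: list[BlockRecord]) -> pd.DataFrame:
    """Clod inventory as a DataFrame (the CSV export layout)."""
    return pd.DataFrame(
        [
            {
                "label": b.label,
                "area_mm2": b.area,
                "length_mm": b.length,
                "width_mm": b.width,
                "height_mm": b.height,
                "equiv_diameter_mm": b.equivalent_diameter,
                "centroid_x_mm": b.centroid[0],
                "centroid_y_mm": b.centroid[1],
            }
            for b in blocks
        ],
        columns=[
            "label",
            "area_mm2",
            "length_mm",
            "width_mm",
            "height_mm",
            "equiv_diameter_mm",
            "centroid_x_mm",
            "centroid_y_mm",
        ],
    )
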