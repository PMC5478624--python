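"""Synthetic graded seedbeds with ground truth, rendered to depth frames.

A seedbed plot of tilth grade g is emulated as a plane (optionally tilted)
carrying discrete convex clods. Clod diameters are drawn from the grade's
size-class composition: a size class is chosen with the composition
probabilities and the diameter is uniform within the class, with the open
classes truncated at the grade's maximum grain size. Clods are rendered as
spherical caps (height = 0.4 x diameter by default) combined by maximum, so
overlapping clods rest on one another; clods are added until their summed
footprint reaches a target coverage of the plot, which mimics spreading
sieved soil over the plot at a roughly constant areal density.

The renderer images the scene with a nadir pinhole depth camera: per-pixel
range, additive Gaussian noise, quantization to the sensor's depth
resolution (2 mm by default, the structured-light resolution near 0.8 m),
and random dropout holes such as strong light produces in the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .blocks import SIZE_CLASS_EDGES
from .camera import (
    DEFAULT_CAMERA_HEIGHT_MM,
    CameraIntrinsics,
    DepthImage,
)
from .errors import GeometryError, InputError, ParameterError
from .grading import GradeReference, load_grade_references
from .roughness import TextureParams, texture_parameters
from .surface import HeightField

#: Smallest clod diameter the generator draws (mm); finer material is part
#: of the basal surface rather than a discrete aggregate.
MIN_CLOD_DIAMETER_MM = 1.0

#: Spherical-cap height as a fraction of clod diameter.
DEFAULT_CAP_ASPECT = 0.4

#: Fraction of the plot the summed clod footprints cover.
DEFAULT_COVERAGE = 0.8

#: Plot extent (x, y) in mm; exceeds the camera footprint at 0.8 m
#: (approximately 874 x 656 mm, off-centre by the principal point) so the
#: frame never sees past the plot edge.
DEFAULT_FIELD_SIZE_MM = (920.0, 700.0)

#: Ground-truth grid pitch, mm.
DEFAULT_SCENE_PITCH_MM = 1.5


@dataclass(frozen=True)
class NoiseModel:
    """Depth-sensor noise: additive Gaussian, quantization, dropout holes."""

    quantization_step: float = 2.0  # mm
    gaussian_sigma: float = 1.5  # mm
    hole_probability: float = 0.02

    def __post_init__(self) -> None:
        if self.quantization_step < 0 or self.gaussian_sigma < 0:
            raise ParameterError("noise magnitudes must be non-negative")
        if not 0 <= self.hole_probability < 1:
            raise ParameterError("hole probability must lie in [0, 1)")


#: Noise-free sensor, for round-trip tests.
NOISELESS = NoiseModel(quantization_step=0.0, gaussian_sigma=0.0, hole_probability=0.0)


@dataclass(frozen=True)
class Clod:
    """Ground truth for one placed clod."""

    center_x: float  # mm, field frame
    center_y: float
    diameter: float  # mm
    height: float  # mm


@dataclass
class SceneGroundTruth:
    """A generated seedbed with full ground truth."""

    true_heightfield: HeightField  # noise-free, field frame
    clods: list[Clod]
    true_texture: TextureParams  # computed on the noise-free field
    grade: int
    seed: int
    field_size_mm: tuple[float, float] = DEFAULT_FIELD_SIZE_MM


def _grade_reference(grade: int, references: list[GradeReference] | None) -> GradeReference:
    refs = references if references is not None else load_grade_references()
    for r in refs:
        if r.grade == grade:
            return r
    raise InputError(f"unknown grade: {grade}")


def sample_grain_sizes(
    grade: int,
    n: int,
    seed: int | np.random.Generator = 0,
    references: list[GradeReference] | None = None,
) -> np.ndarray:
    """Draw n clod diameters (mm) from a grade's size-class composition.

    The size class is multinomial with the composition fractions; within a
    class the diameter is uniform, with every class clipped to
    [MIN_CLOD_DIAMETER_MM, max grain size of the grade].
    """
    if n <= 0:
        raise InputError("n must be positive")
    ref = _grade_reference(grade, references)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = ref.composition.fractions
    p = p / p.sum()
    bins = rng.choice(len(p), size=n, p=p)
    lows = np.maximum(np.array(SIZE_CLASS_EDGES[:-1])[bins], MIN_CLOD_DIAMETER_MM)
    highs = np.minimum(np.array(SIZE_CLASS_EDGES[1:])[bins], ref.max_grain_size)
    highs = np.maximum(highs, lows)  # degenerate class collapses to its edge
    return rng.uniform(lows, highs)


def _paint_caps(
    z: np.ndarray, clods: list[Clod], pitch: float, cap_aspect: float
) -> None:
    """Union (max-composite) spherical caps onto a height grid, in place."""
    ny, nx = z.shape
    for c in clods:
        a = c.diameter / 2.0
        h = c.height
        # sphere through the cap rim of base radius a and apex height h
        R = (a * a + h * h) / (2.0 * h)
        j0 = max(int(np.floor((c.center_x - a) / pitch)), 0)
        j1 = min(int(np.ceil((c.center_x + a) / pitch)) + 1, nx)
        i0 = max(int(np.floor((c.center_y - a) / pitch)), 0)
        i1 = min(int(np.ceil((c.center_y + a) / pitch)) + 1, ny)
        if j0 >= j1 or i0 >= i1:
            continue
        xs = (np.arange(j0, j1) + 0.5) * pitch - c.center_x
        ys = (np.arange(i0, i1) + 0.5) * pitch - c.center_y
        r2 = xs[None, :] ** 2 + ys[:, None] ** 2
        cap = np.sqrt(np.maximum(R * R - r2, 0.0)) - (R - h)
        np.maximum(z[i0:i1, j0:j1], np.where(r2 <= a * a, cap, 0.0), out=z[i0:i1, j0:j1])


def build_seedbed(
    grade: int,
    field_size_mm: tuple[float, float] = DEFAULT_FIELD_SIZE_MM,
    coverage: float = DEFAULT_COVERAGE,
    seed: int = 0,
    pitch_mm: float = DEFAULT_SCENE_PITCH_MM,
    cap_aspect: float = DEFAULT_CAP_ASPECT,
    tilt: tuple[float, float] = (0.0, 0.0),
    n_clods: int | None = None,
    references: list[GradeReference] | None = None,
) -> SceneGroundTruth:
    """Generate one graded seedbed scene with full ground truth.

    Clods are drawn from the grade's composition and placed uniformly at
    random until their summed footprint area reaches ``coverage`` times the
    plot area (or exactly ``n_clods`` clods when given). Because higher
    grades are composed of larger aggregates, mean Sa/Sq of the generated
    surfaces increases with grade, mirroring the field grading.

    Parameters
    ----------
    tilt
        Basal-plane slopes (dz/dx, dz/dy), mm/mm, emulating residual field
        slope/camera tilt; removed by detrending downstream.
    """
    sx, sy = field_size_mm
    if sx <= 0 or sy <= 0:
        raise ParameterError("field size must be positive")
    if not 0 < coverage < 5:
        raise ParameterError("coverage must be positive (and sane)")
    rng = np.random.default_rng(seed)

    plot_area = sx * sy
    diameters: list[float] = []
    if n_clods is not None:
        if n_clods < 0:
            raise ParameterError("n_clods must be >= 0")
        if n_clods > 0:
            diameters = list(sample_grain_sizes(grade, n_clods, rng, references))
    else:
        target = coverage * plot_area
        covered = 0.0
        while covered < target:
            batch = sample_grain_sizes(grade, 512, rng, references)
            areas = np.pi * (batch / 2.0) ** 2
            cum = covered + np.cumsum(areas)
            take = int(np.searchsorted(cum, target)) + 1
            diameters.extend(batch[: min(take, len(batch))])
            covered = float(cum[min(take, len(batch)) - 1])

    clods = [
        Clod(
            center_x=float(rng.uniform(0, sx)),
            center_y=float(rng.uniform(0, sy)),
            diameter=float(d),
            height=float(cap_aspect * d),
        )
        for d in diameters
    ]

    nx = int(round(sx / pitch_mm))
    ny = int(round(sy / pitch_mm))
    xs = (np.arange(nx) + 0.5) * pitch_mm
    ys = (np.arange(ny) + 0.5) * pitch_mm
    # clods rest on the (possibly tilted) basal plane: union of caps first,
    # basal form added afterwards
    z = np.zeros((ny, nx))
    _paint_caps(z, clods, pitch_mm, cap_aspect)
    z += tilt[0] * xs[None, :] + tilt[1] * ys[:, None]

    field = HeightField(z=z, pitch_x=pitch_mm, pitch_y=pitch_mm)
    return SceneGroundTruth(
        true_heightfield=field,
        clods=clods,
        true_texture=texture_parameters(field),
        grade=grade,
        seed=seed,
        field_size_mm=(sx, sy),
    )


def render_depth(
    scene: SceneGroundTruth,
    intrinsics: CameraIntrinsics | None = None,
    camera_height_mm: float = DEFAULT_CAMERA_HEIGHT_MM,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> DepthImage:
    """Image a scene with a nadir depth camera centred over the plot.

    Per-pixel range is found by intersecting the pixel ray with the surface
    (two fixed-point refinements of the ground intersection, ample for
    relief far shallower than the camera height), then corrupted with the
    noise model. Pixels whose ray leaves the plot are holes (0).
    """
    if intrinsics is None:
        intrinsics = CameraIntrinsics()
    hf = scene.true_heightfield
    if camera_height_mm <= float(hf.z.max()):
        raise GeometryError("camera height must exceed the tallest surface point")
    sx, sy = scene.field_size_mm
    rng = np.random.default_rng(seed)

    cols = np.arange(intrinsics.width)
    rows = np.arange(intrinsics.height)
    u = (cols[None, :] - intrinsics.cx) / intrinsics.fx_d  # ray slope x
    v = (rows[:, None] - intrinsics.cy) / intrinsics.fy_d

    def sample_height(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
        ci = gx / hf.pitch_x - 0.5
        ri = gy / hf.pitch_y - 0.5
        return ndimage.map_coordinates(hf.z, [ri, ci], order=1, mode="nearest")

    h = np.zeros((intrinsics.height, intrinsics.width))
    gx = gy = None
    for _ in range(2):
        z_ray = camera_height_mm - h
        gx = sx / 2.0 + u * z_ray
        gy = sy / 2.0 + v * z_ray
        h = sample_height(gx, gy)
    inside = (gx >= 0) & (gx <= sx) & (gy >= 0) & (gy <= sy)

    depth = camera_height_mm - h
    if noise.gaussian_sigma > 0:
        depth = depth + rng.normal(0.0, noise.gaussian_sigma, size=depth.shape)
    if noise.quantization_step > 0:
        depth = np.round(depth / noise.quantization_step) * noise.quantization_step
    if noise.hole_probability > 0:
        inside &= rng.random(depth.shape) >= noise.hole_probability
    depth = np.where(inside, np.maximum(depth, 0.0), 0.0)
    return DepthImage(values=depth, intrinsics=intrinsics)
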