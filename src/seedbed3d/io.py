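"""Readers and writers for the pipeline's standard formats.

Depth frames travel as 16-bit grayscale PNG with the pixel value equal to
range in mm (0 = hole), the native convention of structured-light sensors,
with the camera calibration in a JSON or YAML sidecar. Point clouds and
meshes are exported as ASCII PLY (coordinates in mm); decompositions as a
pair of 16-bit height maps plus JSON metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import trimesh
import yaml

from .camera import DEFAULT_CAMERA_HEIGHT_MM, CameraIntrinsics, DepthImage
from .errors import InputError
from .surface import HeightField, SurfaceDecomposition

#: Fixed-point scale for 16-bit height maps (1/100 mm per count).
_HEIGHT_SCALE = 0.01


def write_depth_png(path: str | Path, image: DepthImage) -> None:
    """Write a depth frame as 16-bit PNG, pixel value = mm."""
    values = np.clip(np.round(image.values), 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), values, extension=".png")


def read_depth_png(
    path: str | Path, intrinsics: CameraIntrinsics | None = None
) -> DepthImage:
    """Read a 16-bit depth PNG; looks for an intrinsics sidecar when none given.

    The sidecar is ``<stem>.json`` or ``<stem>.yaml`` next to the image; if
    absent, the documented default calibration is used.
    """
    path = Path(path)
    arr = np.asarray(iio.imread(path)).astype(float)
    if arr.ndim != 2:
        raise InputError(f"{path} is not a single-channel depth image")
    if intrinsics is None:
        intrinsics, _ = read_intrinsics_sidecar(path)
    return DepthImage(values=arr, intrinsics=intrinsics)


def write_intrinsics_sidecar(
    path: str | Path,
    intrinsics: CameraIntrinsics,
    camera_height_mm: float = DEFAULT_CAMERA_HEIGHT_MM,
) -> None:
    path = Path(path)
    payload = {
        "fx": intrinsics.fx_d,
        "fy": intrinsics.fy_d,
        "cx": intrinsics.cx,
        "cy": intrinsics.cy,
        "width": intrinsics.width,
        "height": intrinsics.height,
        "camera_height_mm": camera_height_mm,
    }
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload))
    else:
        path.write_text(json.dumps(payload, indent=2))


def read_intrinsics_sidecar(
    image_path: str | Path,
) -> tuple[CameraIntrinsics, float]:
    """Locate and parse the calibration sidecar of a depth image.

    Returns (intrinsics, camera_height_mm); both fall back to the package
    defaults when no sidecar exists.
    """
    image_path = Path(image_path)
    for suffix in (".json", ".yaml", ".yml"):
        sidecar = image_path.with_suffix(suffix)
        if sidecar.exists():
            text = sidecar.read_text()
            payload = yaml.safe_load(text) if suffix != ".json" else json.loads(text)
            intr = CameraIntrinsics(
                fx_d=float(payload["fx"]),
                fy_d=float(payload["fy"]),
                cx=float(payload["cx"]),
                cy=float(payload["cy"]),
                width=int(payload.get("width", 640)),
                height=int(payload.get("height", 480)),
            )
            return intr, float(payload.get("camera_height_mm", DEFAULT_CAMERA_HEIGHT_MM))
    return CameraIntrinsics(), DEFAULT_CAMERA_HEIGHT_MM


def write_ply(
    path: str | Path, vertices: np.ndarray, faces: np.ndarray | None = None
) -> None:
    """Export points (and optionally triangles) as ASCII PLY, mm units."""
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    if faces is None:
        cloud = trimesh.PointCloud(vertices)
        cloud.export(str(path), file_type="ply", encoding="ascii")
    else:
        mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
        mesh.export(str(path), encoding="ascii")


def _height_to_u16(z: np.ndarray, valid: np.ndarray, offset: float) -> np.ndarray:
    counts = np.zeros(z.shape, dtype=np.uint16)
    scaled = np.round((z - offset) / _HEIGHT_SCALE) + 1  # 0 reserved for invalid
    counts[valid] = np.clip(scaled[valid], 1, 65535).astype(np.uint16)
    return counts


def write_decomposition(
    directory: str | Path, decomposition: SurfaceDecomposition, stem: str = "surface"
) -> dict:
    """Write basal/block height maps (16-bit PNG) plus JSON metadata.

    Heights are stored as fixed-point 1/100 mm counts above a per-map
    offset recorded in the metadata; 0 marks invalid cells.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"sigma_frac": decomposition.sigma_frac, "height_scale_mm": _HEIGHT_SCALE}
    for name, fieldmap in (("basal", decomposition.basal), ("block", decomposition.block)):
        offset = float(fieldmap.z[fieldmap.valid].min()) if fieldmap.valid.any() else 0.0
        png_path = directory / f"{stem}_{name}.png"
        iio.imwrite(png_path, _height_to_u16(fieldmap.z, fieldmap.valid, offset),
                    extension=".png")
        meta[name] = {
            "path": png_path.name,
            "offset_mm": offset,
            "pitch_x_mm": fieldmap.pitch_x,
            "pitch_y_mm": fieldmap.pitch_y,
        }
    (directory / f"{stem}_decomposition.json").write_text(json.dumps(meta, indent=2))
    return meta


def heightfield_to_vertices(field: HeightField) -> np.ndarray:
    """Valid cells of a height field as an (n, 3) point array, mm."""
    xx, yy = field.cell_coordinates()
    m = field.valid
    return np.column_stack([xx[m], yy[m], field.z[m]])
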