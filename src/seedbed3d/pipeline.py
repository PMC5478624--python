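"""End-to-end composition: depth frame -> texture, grade, clod inventory.

The analysis follows three steps: (1) metric 3D reconstruction of the
surface from the depth frame, (2) separation of the basal ground form from
the protruding soil blocks and extraction of the block inventory, and
(3) ISO 25178-2 height parameters plus tilth-grade assignment.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from . import __version__
from .blocks import (
    FilterSpec,
    binarize_blocks,
    blocks_to_frame,
    label_blocks,
    measure_blocks,
    size_distribution,
)
from .camera import (
    DEFAULT_CAMERA_HEIGHT_MM,
    DepthImage,
    depth_to_point_cloud,
    point_cloud_to_heightfield,
)
from .grading import classify_grade, evaluate_against_reference, load_grade_references
from .io import read_depth_png, read_intrinsics_sidecar, write_decomposition
from .roughness import TextureParams, texture_parameters
from .surface import DEFAULT_SIGMA_FRAC, decompose_surface, detrend

logger = logging.getLogger("seedbed3d")


@dataclass
class PipelineConfig:
    """Everything the single-frame pipeline needs, with field defaults."""

    camera_height_mm: float = DEFAULT_CAMERA_HEIGHT_MM
    grid_pitch_mm: float | None = None  # None -> ground-sample distance
    sigma_frac: float = DEFAULT_SIGMA_FRAC
    threshold_method: str = "otsu"
    threshold_value: float = 0.0
    min_area_cells: int = 4
    seed: int = 0
    output_dir: str | None = None

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(
            sigma_frac=self.sigma_frac,
            threshold_method=self.threshold_method,
            threshold_value=self.threshold_value,
            min_area_cells=self.min_area_cells,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PlotReport:
    """Per-plot pipeline result."""

    plot_id: str
    texture: TextureParams
    grade: int
    n_blocks: int
    blocks: pd.DataFrame
    distribution: dict
    valid_area_mm2: float
    sigma_frac: float
    outputs: dict = dc_field(default_factory=dict)


def analyze_depth_image(
    image: DepthImage, config: PipelineConfig | None = None, plot_id: str = "plot"
) -> PlotReport:
    """Run the full analysis on an in-memory depth frame."""
    config = config or PipelineConfig()
    cloud = depth_to_point_cloud(image)
    field = point_cloud_to_heightfield(
        cloud, camera_height_mm=config.camera_height_mm, grid_pitch_mm=config.grid_pitch_mm
    )
    flat = detrend(field)
    params = texture_parameters(flat, pre_detrended=True)
    decomp = decompose_surface(flat, sigma_frac=config.sigma_frac)
    mask = binarize_blocks(decomp.block, config.filter_spec())
    labels, _ = label_blocks(mask, min_area_cells=config.min_area_cells)
    records = measure_blocks(labels, decomp.block)
    dist = size_distribution(records)
    grade = classify_grade(params)
    return PlotReport(
        plot_id=plot_id,
        texture=params,
        grade=grade,
        n_blocks=len(records),
        blocks=blocks_to_frame(records),
        distribution={
            "bin_edges_mm": [e for e in dist.bin_edges],
            "fractions": dist.fractions.tolist(),
            "n_blocks": dist.n_blocks,
        },
        valid_area_mm2=flat.area,
        sigma_frac=config.sigma_frac,
    )


def run_pipeline(depth_path: str | Path, config: PipelineConfig | None = None) -> PlotReport:
    """Analyze one on-disk depth frame and write the standard reports.

    Writes, under the configured output directory (default: next to the
    input): a texture CSV, a clod-inventory CSV, a size-distribution JSON,
    the decomposition height maps, and a JSON log recording the package
    version and a hash of the effective configuration.
    """
    depth_path = Path(depth_path)
    config = config or PipelineConfig()
    intrinsics, sidecar_height = read_intrinsics_sidecar(depth_path)
    if config.camera_height_mm == DEFAULT_CAMERA_HEIGHT_MM:
        config.camera_height_mm = sidecar_height
    image = read_depth_png(depth_path, intrinsics=intrinsics)
    logger.info(
        "pipeline start: %s (%dx%d, config %s)",
        depth_path.name, image.width, image.height, config.config_hash(),
    )

    report = analyze_depth_image(image, config, plot_id=depth_path.stem)

    out_dir = Path(config.output_dir) if config.output_dir else depth_path.parent
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = depth_path.stem

    texture_csv = out_dir / f"{stem}_texture.csv"
    pd.DataFrame(
        [
            {
                "plot_id": report.plot_id,
                "Sa_mm": report.texture.sa,
                "Sq_mm": report.texture.sq,
                "Ssk": report.texture.ssk,
                "Sku": report.texture.sku,
                "grade": report.grade,
                "valid_area_mm2": report.valid_area_mm2,
                "sigma_used": report.sigma_frac,
            }
        ]
    ).to_csv(texture_csv, index=False)

    blocks_csv = out_dir / f"{stem}_blocks.csv"
    report.blocks.to_csv(blocks_csv, index=False)

    dist_json = out_dir / f"{stem}_distribution.json"
    dist_json.write_text(json.dumps(report.distribution, indent=2))

    # the decomposition maps are recomputed here only for export
    cloud = depth_to_point_cloud(image)
    field = point_cloud_to_heightfield(
        cloud, camera_height_mm=config.camera_height_mm, grid_pitch_mm=config.grid_pitch_mm
    )
    decomp = decompose_surface(detrend(field), sigma_frac=config.sigma_frac)
    write_decomposition(out_dir, decomp, stem=stem)

    log_json = out_dir / f"{stem}_run.json"
    log_json.write_text(
        json.dumps(
            {
                "input": depth_path.name,
                "version": __version__,
                "config_hash": config.config_hash(),
                "config": {k: v for k, v in config.__dict__.items()},
            },
            indent=2,
            default=str,
        )
    )
    report.outputs = {
        "texture_csv": str(texture_csv),
        "blocks_csv": str(blocks_csv),
        "distribution_json": str(dist_json),
        "run_log": str(log_json),
    }
    return report


def run_validation(
    sensor_csv: str | Path,
    manual_csv: str | Path,
    out_csv: str | Path | None = None,
    split_fraction: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Score per-plot sensor texture against a manual reference table.

    Both CSVs need columns plot_id, grade, Sa_mm, Sq_mm. Returns (and
    optionally writes) the parameter x grade-group x dataset report.
    """
    sensor = pd.read_csv(sensor_csv)
    manual = pd.read_csv(manual_csv)
    report = evaluate_against_reference(
        sensor, manual, split_fraction=split_fraction, seed=seed
    )
    if out_csv is not None:
        report.to_csv(out_csv, index=False)
    return report
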