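"""Tilth grading and sensor-vs-manual validation statistics.

Seedbeds are classified into 10 tilth grades defined by sieved clod-size
composition; each grade carries characteristic areal-texture values. Since
Sa and Sq discriminate the grades while Ssk and Sku do not, classification
is nearest-reference in standardized (Sa, Sq) space.

Agreement between sensor-derived and manually measured (pin-meter)
parameters is scored with R^2 (squared Pearson correlation), RMSE, and REP
(RMSE as a percentage of the reference mean), under a seeded
calibration/validation split stratified by grade.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import SIZE_CLASS_EDGES, SizeDistribution
from .errors import InputError, UndefinedStatisticError
from .roughness import TextureParams

#: Grade groupings used in validation reports: fine, medium, coarse tilth.
DEFAULT_GRADE_GROUPS = {"1-3": (1, 2, 3), "4-6": (4, 5, 6), "7-10": (7, 8, 9, 10)}


@dataclass(frozen=True)
class GradeReference:
    """One tilth grade: size composition plus characteristic texture values."""

    grade: int
    max_grain_size: float  # mm
    composition: SizeDistribution
    sa_ref: float
    sq_ref: float
    ssk_ref: float
    sku_ref: float


def _data_path(name: str):
    return importlib.resources.files("seedbed3d.data").joinpath(name)


def load_composition_table() -> pd.DataFrame:
    """Packaged grade/size-composition table (fractions in percent)."""
    with importlib.resources.as_file(_data_path("grade_compositions.csv")) as p:
        return pd.read_csv(p)


def load_texture_table() -> pd.DataFrame:
    """Packaged characteristic texture values per grade (Sa/Sq in mm)."""
    with importlib.resources.as_file(_data_path("grade_texture.csv")) as p:
        return pd.read_csv(p)


def load_grade_references() -> list[GradeReference]:
    """Build the 10 GradeReference records from the packaged tables."""
    comp = load_composition_table().set_index("grade")
    tex = load_texture_table().set_index("grade")
    frac_cols = [c for c in comp.columns if c.startswith("frac_")]
    refs = []
    for grade in comp.index:
        fractions = comp.loc[grade, frac_cols].to_numpy(dtype=float) / 100.0
        refs.append(
            GradeReference(
                grade=int(grade),
                max_grain_size=float(comp.loc[grade, "max_grain_size_mm"]),
                composition=SizeDistribution(
                    fractions=fractions,
                    n_blocks=0,
                    bin_edges=SIZE_CLASS_EDGES,
                ),
                sa_ref=float(tex.loc[grade, "Sa_mm"]),
                sq_ref=float(tex.loc[grade, "Sq_mm"]),
                ssk_ref=float(tex.loc[grade, "Ssk"]),
                sku_ref=float(tex.loc[grade, "Sku"]),
            )
        )
    return refs


def classify_grade(
    params: TextureParams, references: list[GradeReference] | None = None
) -> int:
    """Assign the tilth grade whose (Sa, Sq) reference is nearest.

    Distances are computed in standardized space (each axis divided by the
    standard deviation of the reference values on that axis) so that Sa and
    Sq contribute comparably; ties break toward the lower grade.
    """
    if references is None:
        references = load_grade_references()
    if not references:
        raise InputError("reference list is empty")
    if not (np.isfinite(params.sa) and np.isfinite(params.sq)):
        raise InputError("classification requires finite Sa and Sq")
    sa_refs = np.array([r.sa_ref for r in references])
    sq_refs = np.array([r.sq_ref for r in references])
    sa_scale = np.std(sa_refs) or 1.0
    sq_scale = np.std(sq_refs) or 1.0
    d2 = ((params.sa - sa_refs) / sa_scale) ** 2 + ((params.sq - sq_refs) / sq_scale) ** 2
    grades = np.array([r.grade for r in references])
    # stable argmin over grade order implements the low-grade tie rule
    order = np.argsort(grades, kind="stable")
    best = order[int(np.argmin(d2[order]))]
    return int(grades[best])


def _as_arrays(estimates, reference) -> tuple[np.ndarray, np.ndarray]:
    e = np.asarray(estimates, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if e.shape != r.shape:
        raise InputError(f"series lengths differ: {e.size} vs {r.size}")
    return e, r


def r_squared(estimates, reference, method: str = "pearson") -> float:
    """Coefficient of determination between two series.

    ``method="pearson"`` (default) returns the squared Pearson correlation,
    the quantity read off a 1:1 scatter; ``method="sse"`` returns
    1 - SSE/SST, which penalizes bias. On a fitted line the two coincide.
    """
    e, r = _as_arrays(estimates, reference)
    if e.size < 3:
        raise InputError("need at least 3 paired observations")
    if np.ptp(e) == 0 or np.ptp(r) == 0:
        raise UndefinedStatisticError("R^2 undefined for a constant series")
    if method == "pearson":
        return float(np.corrcoef(e, r)[0, 1] ** 2)
    if method == "sse":
        sse = np.sum((r - e) ** 2)
        sst = np.sum((r - r.mean()) ** 2)
        return float(1.0 - sse / sst)
    raise InputError(f"unknown R^2 method: {method}")


def rmse(estimates, reference) -> float:
    """Root-mean-square error between two equally long series."""
    e, r = _as_arrays(estimates, reference)
    if e.size == 0:
        raise InputError("need at least one paired observation")
    return float(np.sqrt(np.mean((e - r) ** 2)))


def rep(estimates, reference) -> float:
    """Relative error of prediction: 100 * RMSE / mean(reference), percent."""
    e, r = _as_arrays(estimates, reference)
    m = r.mean()
    if m == 0:
        raise UndefinedStatisticError("REP undefined when the reference mean is 0")
    return float(100.0 * rmse(e, r) / m)


def split_calibration_validation(
    records: pd.DataFrame,
    fraction: float = 0.5,
    seed: int = 0,
    stratify_by: str | None = "grade",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random split into calibration and validation sets.

    The split is stratified by the ``stratify_by`` column (grade by
    default) so every grade contributes to both sets; strata with fewer
    than 2 records fall back to an unstratified draw.
    """
    if not 0 < fraction < 1:
        raise InputError("fraction must lie in (0, 1)")
    if len(records) < 2:
        raise InputError("need at least 2 records to split")
    rng = np.random.default_rng(seed)

    def _draw(df: pd.DataFrame) -> np.ndarray:
        n_cal = int(round(fraction * len(df)))
        n_cal = min(max(n_cal, 1 if len(df) > 1 else 0), len(df) - 1) if len(df) > 1 else n_cal
        perm = rng.permutation(len(df))
        return df.index.to_numpy()[perm[:n_cal]]

    if stratify_by is not None and stratify_by in records.columns:
        groups = [g for _, g in records.groupby(stratify_by, sort=True)]
        if all(len(g) >= 2 for g in groups):
            cal_idx = np.concatenate([_draw(g) for g in groups])
        else:
            cal_idx = _draw(records)
    else:
        cal_idx = _draw(records)

    cal_mask = records.index.isin(cal_idx)
    return records[cal_mask], records[~cal_mask]


def evaluate_against_reference(
    sensor: pd.DataFrame,
    manual: pd.DataFrame,
    grade_groups: dict[str, tuple[int, ...]] | None = None,
    parameters: tuple[str, ...] = ("Sa_mm", "Sq_mm"),
    split_fraction: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Score sensor-derived texture against manual reference per grade group.

    Both frames need ``plot_id``, ``grade`` and the parameter columns.
    Plots are joined on ``plot_id`` (an error lists any unmatched ids),
    split into calibration/validation sets, and R^2, RMSE and REP are
    reported per parameter x grade group x dataset.
    """
    if grade_groups is None:
        grade_groups = DEFAULT_GRADE_GROUPS
    s_ids = set(sensor["plot_id"])
    m_ids = set(manual["plot_id"])
    if s_ids != m_ids:
        offenders = sorted(s_ids.symmetric_difference(m_ids))
        raise InputError(f"unmatched plot ids: {offenders}")
    merged = sensor.merge(manual, on="plot_id", suffixes=("_sensor", "_manual"))
    merged["grade"] = merged["grade_sensor"] if "grade_sensor" in merged else merged["grade"]
    # canonical order: the report must not depend on input record order
    merged = merged.sort_values("plot_id").reset_index(drop=True)

    cal, val = split_calibration_validation(merged, fraction=split_fraction, seed=seed)
    rows = []
    for dataset, df in (("calibration", cal), ("validation", val)):
        for param in parameters:
            for group_label, grades in grade_groups.items():
                sub = df[df["grade"].isin(grades)]
                est = sub[f"{param}_sensor"].to_numpy()
                ref = sub[f"{param}_manual"].to_numpy()
                rows.append(
                    {
                        "parameter": param.removesuffix("_mm"),
                        "grade_group": group_label,
                        "dataset": dataset,
                        "n": len(sub),
                        "R2": r_squared(est, ref),
                        "RMSE": rmse(est, ref),
                        "REP_percent": rep(est, ref),
                    }
                )
    return pd.DataFrame(rows)
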