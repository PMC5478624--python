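"""ISO 25178-2 areal height parameters on detrended height fields.

Over the valid evaluation area A, with z(x, y) the height deviation from the
least-squares mean plane:

    Sa  = (1/A) integral |z| dx dy          arithmetical mean height, mm
    Sq  = sqrt((1/A) integral z^2 dx dy)    root-mean-square height, mm
    Ssk = (1/Sq^3) (1/A) integral z^3       skewness, dimensionless
    Sku = (1/Sq^4) (1/A) integral z^4       kurtosis, dimensionless

Sku is the plain fourth standardized moment (a Gaussian surface gives 3,
not 0). Integrals are evaluated as cell sums times cell area with invalid
cells excluded from both the integral and A, which makes every parameter a
plain moment of the valid-cell height sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedStatisticError
from .surface import HeightField, detrend


@dataclass(frozen=True)
class TextureParams:
    """The (Sa, Sq, Ssk, Sku) tuple for one surface.

    Ssk and Sku are NaN on a perfectly flat surface (Sq = 0), where the
    standardized moments are undefined.
    """

    sa: float
    sq: float
    ssk: float
    sku: float

    def __post_init__(self) -> None:
        if self.sa < 0:
            raise UndefinedStatisticError("Sa must be non-negative")
        # power-mean inequality; small float slack
        if self.sq < self.sa * (1 - 1e-9):
            raise UndefinedStatisticError("Sq must be >= Sa")
        if math.isfinite(self.sku) and math.isfinite(self.ssk):
            if self.sku < self.ssk**2 + 1 - 1e-9:
                raise UndefinedStatisticError("moment inequality Sku >= Ssk^2 + 1 violated")


def _check_area(field: HeightField) -> np.ndarray:
    z = field.valid_values()
    if z.size == 0:
        raise UndefinedStatisticError("evaluation area A is empty")
    return z


def compute_sa(field: HeightField) -> float:
    """Arithmetical mean height Sa (mm) of a detrended field."""
    return float(np.mean(np.abs(_check_area(field))))


def compute_sq(field: HeightField) -> float:
    """Root-mean-square height Sq (mm) of a detrended field."""
    return float(np.sqrt(np.mean(_check_area(field) ** 2)))


def compute_ssk(field: HeightField) -> float:
    """Skewness Ssk of the height distribution; raises when Sq = 0."""
    z = _check_area(field)
    sq = np.sqrt(np.mean(z**2))
    if sq == 0:
        raise UndefinedStatisticError("Ssk undefined on a flat surface (Sq = 0)")
    return float(np.mean(z**3) / sq**3)


def compute_sku(field: HeightField) -> float:
    """Kurtosis Sku (Gaussian surface -> 3); raises when Sq = 0."""
    z = _check_area(field)
    sq = np.sqrt(np.mean(z**2))
    if sq == 0:
        raise UndefinedStatisticError("Sku undefined on a flat surface (Sq = 0)")
    return float(np.mean(z**4) / sq**4)


def texture_parameters(field: HeightField, pre_detrended: bool = False) -> TextureParams:
    """Compute all four height parameters in one pass.

    The field is plane-detrended internally unless ``pre_detrended`` is set,
    so heights are measured from the least-squares mean plane regardless of
    the datum of the input. On a perfectly flat (residual) surface Ssk and
    Sku are returned as NaN rather than raising, for batch robustness.
    """
    if not pre_detrended:
        field = detrend(field)
    z = _check_area(field)
    z = z - z.mean()  # guard against residual datum offset
    sa = float(np.mean(np.abs(z)))
    sq = float(np.sqrt(np.mean(z**2)))
    # below ~1e-9 mm the "relief" is pure floating-point cancellation noise
    # from the plane fit, so the standardized moments are meaningless
    if sq < 1e-9:
        return TextureParams(sa=sa, sq=sq, ssk=float("nan"), sku=float("nan"))
    ssk = float(np.mean(z**3) / sq**3)
    sku = float(np.mean(z**4) / sq**4)
    return TextureParams(sa=sa, sq=sq, ssk=ssk, sku=sku)
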