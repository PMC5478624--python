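"""Emergence bookkeeping: rate and speed summaries per plot.

Daily cumulative seedling counts are condensed into the establishment
descriptors used to link seedbed tilth to crop performance: the emergence
rate (final emerged seedlings as a percentage of seeds sown, optionally
viability-adjusted) and emergence speed, operationalized as the first day
on which cumulative emergence crosses given fractions of its final value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass
class EmergenceSeries:
    """Daily cumulative emergence counts for one plot."""

    plot_id: str
    grade: int
    cultivar: str
    seeds_sown: int
    days: np.ndarray  # days after sowing
    cumulative_emerged: np.ndarray
    seed_viability: float = 1.0  # germinable fraction of sown seed

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.cumulative_emerged = np.asarray(self.cumulative_emerged, dtype=float)
        if self.days.shape != self.cumulative_emerged.shape:
            raise InputError("days and counts must be equally long")
        if np.any(np.diff(self.cumulative_emerged) < 0):
            raise InputError("cumulative emergence must be non-decreasing")
        if self.cumulative_emerged.size and self.cumulative_emerged[-1] > self.seeds_sown:
            raise InputError("emerged count exceeds seeds sown")
        if not 0 < self.seed_viability <= 1:
            raise InputError("seed viability must lie in (0, 1]")


def emergence_rate(series: EmergenceSeries, viability_adjusted: bool = False) -> float:
    """Final emergence as a percentage of sown (or viable) seeds."""
    if series.seeds_sown <= 0:
        raise InputError("seeds_sown must be positive")
    denom = series.seeds_sown * (series.seed_viability if viability_adjusted else 1.0)
    final = series.cumulative_emerged[-1] if series.cumulative_emerged.size else 0.0
    return float(100.0 * final / denom)


@dataclass
class EmergenceSpeed:
    """Threshold-crossing summary of an emergence curve (days after sowing)."""

    first_emergence_day: int | None
    day_of_max: int | None
    threshold_days: dict[float, int] = field(default_factory=dict)

    @property
    def no_emergence(self) -> bool:
        return self.first_emergence_day is None


def emergence_speed(
    series: EmergenceSeries, thresholds: tuple[float, ...] = (0.5, 0.9)
) -> EmergenceSpeed:
    """Days to reach given fractions of the final emergence.

    For each threshold t in (0, 1], reports the first recorded day on which
    cumulative emergence >= t * final emergence, along with the
    first-emergence day and the day the curve reaches its maximum. A plot
    with zero emergence is flagged rather than raising.
    """
    if any(not 0 < t <= 1 for t in thresholds):
        raise InputError("thresholds must lie in (0, 1]")
    counts = series.cumulative_emerged
    final = counts[-1] if counts.size else 0.0
    if final <= 0:
        return EmergenceSpeed(first_emergence_day=None, day_of_max=None)
    first_day = int(series.days[np.argmax(counts > 0)])
    day_of_max = int(series.days[np.argmax(counts >= final)])
    crossing = {
        float(t): int(series.days[np.argmax(counts >= t * final)]) for t in thresholds
    }
    return EmergenceSpeed(
        first_emergence_day=first_day, day_of_max=day_of_max, threshold_days=crossing
    )
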