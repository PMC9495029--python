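"""Batch-recipe timing, staggered-campaign Gantt generation and annualization.

The plant runs a long-term batch campaign: one recipe (about 7.25 h of
occupied equipment time per batch) is re-started every cycle time (2.75 h),
so consecutive batches overlap on different equipment.  Over an annual
operating window of 7919 h this stagger yields 2878 batches per year, and
per-batch bulk-material consumptions scale linearly to annual totals.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

__all__ = [
    "Recipe",
    "ScheduleSummary",
    "SchedulingError",
    "EquipmentConflictError",
    "n_batches",
    "build_gantt",
    "annualize",
    "default_recipe",
    "DEFAULT_ANNUAL_OPERATING_TIME",
]

#: Annual operating hours (330 days), leaving downtime for maintenance.
DEFAULT_ANNUAL_OPERATING_TIME = 7919.0


class SchedulingError(ValueError):
    """Invalid recipe or schedule parameters."""


class EquipmentConflictError(SchedulingError):
    """A unit's occupancy intervals overlap between staggered batches."""


@dataclass(frozen=True)
class Recipe:
    """Ordered unit operations of one batch with their start offsets.

    ``operations`` holds (unit_id, duration_h, offset_h) tuples; ``batch_time``
    is the end of the last operation and ``cycle_time`` the stagger between
    consecutive batch starts.
    """

    operations: tuple[tuple[str, float, float], ...]
    batch_time: float
    cycle_time: float

    def __post_init__(self) -> None:
        if self.cycle_time <= 0:
            raise SchedulingError(f"cycle_time={self.cycle_time} must be > 0")
        if self.cycle_time > self.batch_time:
            raise SchedulingError(
                f"cycle_time {self.cycle_time} exceeds batch_time {self.batch_time}"
            )
        if self.operations:
            makespan = max(off + dur for _, dur, off in self.operations)
            if self.batch_time + 1e-9 < makespan:
                raise SchedulingError(
                    f"batch_time {self.batch_time} shorter than last operation end {makespan}"
                )
        for uid, dur, off in self.operations:
            if dur < 0 or off < 0:
                raise SchedulingError(f"{uid}: negative duration or offset")


@dataclass(frozen=True)
class ScheduleSummary:
    """Annual operating time, batch/cycle times and resulting batches per year."""

    annual_operating_time: float
    batch_time: float
    cycle_time: float
    n_batches: int

    def __post_init__(self) -> None:
        if self.n_batches < 0 or self.n_batches != int(self.n_batches):
            raise SchedulingError(f"n_batches={self.n_batches} must be a non-negative integer")


def n_batches(annual_operating_time: float, batch_time: float, cycle_time: float) -> int:
    """Number of staggered batches fitting in the annual operating window.

    The first batch occupies ``batch_time``; each further batch adds one
    ``cycle_time``, so the count is
    ``floor((annual_operating_time - batch_time) / cycle_time) + 1``.
    Returns 0 (with a warning) when not even one batch fits.
    """
    if annual_operating_time <= 0 or batch_time <= 0 or cycle_time <= 0:
        raise SchedulingError("all timing inputs must be > 0")
    if batch_time > annual_operating_time:
        _warnings.warn(
            f"batch_time {batch_time} h exceeds annual operating time "
            f"{annual_operating_time} h; zero batches scheduled",
            stacklevel=2,
        )
        return 0
    return int((annual_operating_time - batch_time) // cycle_time) + 1


def build_gantt(recipe: Recipe, n: int) -> list[tuple[int, str, float, float]]:
    """Expand a recipe into per-batch (batch_index, unit_id, start, end) entries.

    Batch ``k`` is shifted by ``k x cycle_time``.  Raises
    :class:`EquipmentConflictError` naming the first unit whose occupancy
    windows overlap between batches — which happens exactly when an
    operation's duration exceeds the cycle time.
    """
    if n < 1:
        raise SchedulingError(f"n={n} must be >= 1")
    if n > 1:
        for uid, dur, _off in recipe.operations:
            if dur > recipe.cycle_time + 1e-9:
                raise EquipmentConflictError(
                    f"unit {uid}: operation duration {dur} h exceeds cycle time "
                    f"{recipe.cycle_time} h; staggered batches would overlap"
                )
    entries = []
    for k in range(n):
        shift = k * recipe.cycle_time
        for uid, dur, off in recipe.operations:
            entries.append((k, uid, off + shift, off + dur + shift))
    return entries


def annualize(per_batch: dict[str, float], n: int) -> dict[str, float]:
    """Scale per-batch material masses (kg/batch) to annual totals (kg/yr)."""
    if n < 0:
        raise SchedulingError(f"n={n} must be >= 0")
    for name, m in per_batch.items():
        if m < 0:
            raise SchedulingError(f"{name}: negative per-batch mass {m}")
    return {name: m * n for name, m in per_batch.items()}


def default_recipe() -> Recipe:
    """The default plant recipe: 7.25 h batch time, 2.75 h cycle time.

    Main stages run for one hour each in sequence; the fractionation train,
    condensers, adsorber, freeze dryer and transport overlap semi-continuously
    downstream with pull-in/transfer-in steps under one hour.  The individual
    offsets are a configuration fixture — only the 7.25 h batch time and the
    2.75 h cycle time are schedule-defining.
    """
    ops = (
        ("WSH-101", 1.0, 0.0),
        ("GR-101", 1.0, 1.0),
        ("BR-101", 1.0, 2.0),
        ("MF-101", 1.0, 3.0),
        ("MF-102", 1.0, 4.0),
        ("DC-101", 1.0, 5.0),
        ("UF-101", 1.0, 6.0),
        ("C-101", 1.0, 6.0),
        ("HX-101", 0.75, 6.25),
        ("GAC-101", 0.25, 7.0),
        ("C-102", 0.75, 6.25),
        ("HX-104", 0.5, 6.5),
        ("C-103", 0.5, 6.5),
        ("HX-102", 0.5, 6.75),
        ("HX-103", 0.5, 6.75),
        ("FDR-101", 1.0, 6.0),
        ("P-11", 0.25, 7.0),
    )
    return Recipe(operations=ops, batch_time=7.25, cycle_time=2.75)
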