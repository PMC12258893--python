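"""Percent-GFP-positive trajectories and silencing-memory half-lives.

The half-life of RNAi silencing memory is the interpolated coordinate —
measured in generations since trigger removal, or in days — at which 50% of
scored individuals re-express the GFP reporter. For each replicate series the
two scoring time points closest below and closest above the threshold are
selected and the crossing of the straight line through them is returned.

Series that oscillate around the threshold (more than one crossing) fall back
to a smoothed bracket using points further apart: the last sub-threshold point
before the sustained recovery and the first point of that sustained recovery.
Series that never sustainedly reach the threshold are right-censored; series
already above the threshold at the first scored generation are anchored
against the fully silenced G0 point (0% at coordinate 0).

The day axis maps generation indices through a :class:`GenerationSchedule`,
which carries a per-temperature generation time and any developmental arrests
(L1 starvation arrest, dauer diapause) that insert extra days at a given
generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    GroupingError,
    LeftAnchored,
    RightCensored,
    ScheduleError,
    ValidationError,
)
from .scoring import GroupKey, ScoringRecord

#: Default generation times in days. The assay transfers L4 larvae every
#: generation; ~3.5 d per generation at 20 °C and ~2.5 d at 25 °C are typical
#: C. elegans egg-to-egg times. Only relative/arrest arithmetic is asserted.
DEFAULT_BASE_DAYS: Mapping[str, float] = {"20C": 3.5, "25C": 2.5}


@dataclass(frozen=True)
class GenerationSchedule:
    """Maps generation index to days since G0 for one environment.

    Parameters
    ----------
    base_days
        Days per generation, keyed by temperature label.
    arrests
        ``(generation_index, extra_days)`` pairs; each arrest adds its extra
        days to the day coordinate of every generation at or after its index
        (e.g. a 6-day L1 starvation arrest at G1, or a 5-day dauer diapause).
    """

    base_days: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_DAYS))
    arrests: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_days", dict(self.base_days))
        object.__setattr__(
            self, "arrests", tuple((int(g), float(d)) for g, d in self.arrests)
        )
        for label, days in self.base_days.items():
            if days <= 0:
                raise ScheduleError(f"base_days[{label!r}] must be > 0, got {days}")
        for g, extra in self.arrests:
            if g < 0:
                raise ScheduleError(f"arrest generation must be >= 0, got {g}")
            if extra < 0:
                raise ScheduleError(f"arrest extra_days must be >= 0, got {extra}")


def day_of_generation(schedule: GenerationSchedule, g: int, temperature: str) -> float:
    """Days elapsed since G0 at generation ``g`` under ``schedule``.

    ``day(0) = 0``; each generation adds the temperature's base duration and
    each arrest at a generation <= g adds its extra days.
    """
    if temperature not in schedule.base_days:
        raise ScheduleError(
            f"unknown temperature label {temperature!r}; "
            f"known: {sorted(schedule.base_days)}"
        )
    if g < 0:
        raise ValidationError(f"generation index must be >= 0 on the day axis, got {g}")
    base = schedule.base_days[temperature]
    extra = sum(d for gi, d in schedule.arrests if gi <= g)
    return g * base + extra


def pct_gfp_positive(n_off: int, n_dim: int, n_on: int) -> float:
    """Percent GFP-positive among scored individuals.

    OFF and DIM are grouped as GFP-negative: DIM individuals are still
    inheriting silencing, so only fully ON animals count as positive.
    """
    total = n_off + n_dim + n_on
    if total < 1:
        raise ValidationError("percent GFP-positive is undefined for zero scored individuals")
    return 100.0 * n_on / total


@dataclass(frozen=True)
class TrajectoryPoint:
    generation: int
    day: float
    pct_on: float


@dataclass(frozen=True)
class Trajectory:
    """Ordered per-replicate series of (generation, day, percent GFP-positive)."""

    key: GroupKey
    points: tuple[TrajectoryPoint, ...]

    def __post_init__(self) -> None:
        gens = [p.generation for p in self.points]
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValidationError("trajectory generations must be strictly increasing")
        days = [p.day for p in self.points]
        if any(b < a for a, b in zip(days, days[1:])):
            raise ValidationError("trajectory days must be non-decreasing")
        for p in self.points:
            if not (0.0 <= p.pct_on <= 100.0):
                raise ValidationError(f"pct_on out of [0, 100]: {p.pct_on}")


def build_trajectory(
    records: Sequence[ScoringRecord],
    schedule: GenerationSchedule,
    temperature: str = "20C",
) -> Trajectory:
    """Turn one replicate's scoring records into a trajectory.

    All records must share a group key. Records at generation < 0 (the G-1
    exposed generation) are design metadata and are dropped.
    """
    if not records:
        raise ValidationError("cannot build a trajectory from zero records")
    keys = {r.group_key for r in records}
    if len(keys) > 1:
        raise GroupingError(f"records mix group keys: {sorted(keys)}")
    kept = sorted((r for r in records if r.generation >= 0), key=lambda r: r.generation)
    if not kept:
        raise ValidationError("no records at generation >= 0")
    points = tuple(
        TrajectoryPoint(
            generation=r.generation,
            day=day_of_generation(schedule, r.generation, temperature),
            pct_on=pct_gfp_positive(r.n_off, r.n_dim, r.n_on),
        )
        for r in kept
    )
    return Trajectory(key=keys.pop(), points=points)


def _crossing_count(above: Sequence[bool]) -> int:
    return sum(1 for a, b in zip(above, above[1:]) if a != b)


def select_bracket(
    points: Sequence[TrajectoryPoint], threshold: float = 50.0
) -> tuple[TrajectoryPoint, TrajectoryPoint, bool]:
    """Select the two points bracketing the threshold crossing.

    Default rule: the below point minimizes ``threshold - value`` among points
    strictly below the threshold, the above point minimizes
    ``value - threshold`` among points at or above it (a value exactly at the
    threshold counts as above). Ties prefer the later generation below and the
    earlier generation above (tightest bracket).

    Oscillation rule (fires iff the series crosses the threshold more than
    once): the bracket is widened to the last sub-threshold point and the
    first point from which all later values stay at or above the threshold.

    Raises
    ------
    RightCensored
        If no point reaches the threshold, or the series ends below it (no
        sustained recovery exists to bracket).
    LeftAnchored
        If every point is already at or above the threshold.
    """
    if not points:
        raise ValidationError("cannot bracket an empty series")
    above = [p.pct_on >= threshold for p in points]
    if not any(above):
        raise RightCensored("trajectory never reaches the threshold")
    if all(above):
        raise LeftAnchored("trajectory starts at or above the threshold")
    if not above[-1]:
        raise RightCensored("trajectory ends below the threshold (no sustained recovery)")

    if _crossing_count(above) == 1:
        below_idx = max(
            range(len(points)),
            key=lambda i: (-1e300, 0) if above[i] else (points[i].pct_on, i),
        )
        above_idx = min(
            (i for i in range(len(points)) if above[i]),
            key=lambda i: (points[i].pct_on, i),
        )
        return points[below_idx], points[above_idx], False

    # Oscillation: first index from which every value stays >= threshold;
    # the point before it is, by minimality, the last sub-threshold point.
    j = len(points) - 1
    while j > 0 and above[j - 1]:
        j -= 1
    return points[j - 1], points[j], True


@dataclass(frozen=True)
class HalfLifeEstimate:
    """Interpolated 50%-crossing of a silencing-memory trajectory.

    ``value`` is on the requested axis (generations or days); absent iff
    ``status == "censored"``. ``status`` is ``"left_anchored"`` when the
    below point of the bracket is the G0 point (observed or assumed 0%).
    """

    key: GroupKey
    axis: str
    value: float | None
    status: str
    bracket: tuple[tuple[float, float], tuple[float, float]] | None
    smoothing_applied: bool

    def __post_init__(self) -> None:
        if (self.value is None) != (self.status == "censored"):
            raise ValidationError("value must be absent iff status is censored")


def half_life(
    trajectory: Trajectory, axis: str = "generations", threshold: float = 50.0
) -> HalfLifeEstimate:
    """Interpolated coordinate at which the trajectory crosses the threshold.

    With bracket ``((x_b, v_b), (x_a, v_a))`` on the chosen axis the estimate
    is ``x_b + (threshold - v_b) * (x_a - x_b) / (v_a - v_b)``; a point exactly
    at the threshold is the above point, so its coordinate is returned
    exactly. Trajectories already above the threshold at their first point are
    bracketed against G0 (0% at coordinate 0) unless an observed G0 point is
    present. Trajectories that never sustainedly reach the threshold are
    censored (no value).
    """
    if axis not in ("generations", "days"):
        raise ValidationError(f"axis must be 'generations' or 'days', got {axis!r}")
    points = trajectory.points
    smoothing = False
    try:
        below, above_pt, smoothing = select_bracket(points, threshold)
    except RightCensored:
        return HalfLifeEstimate(
            key=trajectory.key,
            axis=axis,
            value=None,
            status="censored",
            bracket=None,
            smoothing_applied=False,
        )
    except LeftAnchored:
        below = TrajectoryPoint(generation=0, day=0.0, pct_on=0.0)
        candidates = [p for p in points if p.generation > 0]
        if not candidates:
            raise ValidationError(
                "trajectory is above the threshold at G0 with no later points"
            ) from None
        above_pt = min(candidates, key=lambda p: (p.pct_on, p.generation))

    def coord(p: TrajectoryPoint) -> float:
        return float(p.generation) if axis == "generations" else p.day

    x_b, v_b = coord(below), below.pct_on
    x_a, v_a = coord(above_pt), above_pt.pct_on
    value = x_b + (threshold - v_b) * (x_a - x_b) / (v_a - v_b)
    status = "left_anchored" if below.generation == 0 else "interpolated"
    return HalfLifeEstimate(
        key=trajectory.key,
        axis=axis,
        value=float(value),
        status=status,
        bracket=((x_b, v_b), (x_a, v_a)),
        smoothing_applied=smoothing,
    )


def summarize_trajectories(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Pointwise mean and sample SD of pct_on across replicate trajectories.

    All trajectories must share the same generation grid (no imputation);
    the sample SD is 0 for a single replicate.
    """
    if not trajectories:
        raise ValidationError("no trajectories to summarize")
    grids = [tuple(p.generation for p in t.points) for t in trajectories]
    if len(set(grids)) > 1:
        raise AlignmentError(f"inconsistent generation grids: {sorted(set(grids))}")
    days = [tuple(p.day for p in t.points) for t in trajectories]
    if len(set(days)) > 1:
        raise AlignmentError("inconsistent day coordinates across replicates")
    values = np.array([[p.pct_on for p in t.points] for t in trajectories])
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1) if len(trajectories) > 1 else np.zeros(values.shape[1])
    return pd.DataFrame(
        {
            "generation": list(grids[0]),
            "day": list(days[0]),
            "mean_pct": mean,
            "sd_pct": sd,
        }
    )


def halflife_table(
    groups: Mapping[GroupKey, Sequence[ScoringRecord]],
    schedules: Mapping[str, tuple[GenerationSchedule, str]],
    axes: Iterable[str] = ("generations",),
    threshold: float = 50.0,
) -> pd.DataFrame:
    """Compute half-lives for every replicate group on each requested axis.

    ``schedules`` maps environment label to (schedule, temperature). Returns
    the canonical half-life result table with columns
    ``block,strain,environment,replicate,axis,value,status,g_below,g_above,smoothing``.
    """
    rows = []
    for key, records in groups.items():
        if key.environment not in schedules:
            raise ScheduleError(
                f"no schedule for environment {key.environment!r}; "
                f"known: {sorted(schedules)}"
            )
        schedule, temperature = schedules[key.environment]
        traj = build_trajectory(records, schedule, temperature)
        for axis in axes:
            est = half_life(traj, axis=axis, threshold=threshold)
            if est.bracket is None:
                g_below = g_above = math.nan
            else:
                g_below, g_above = est.bracket[0][0], est.bracket[1][0]
            rows.append(
                {
                    "block": key.block,
                    "strain": key.strain,
                    "environment": key.environment,
                    "replicate": key.replicate,
                    "axis": axis,
                    "value": est.value if est.value is not None else math.nan,
                    "status": est.status,
                    "g_below": g_below,
                    "g_above": g_above,
                    "smoothing": est.smoothing_applied,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "block",
            "strain",
            "environment",
            "replicate",
            "axis",
            "value",
            "status",
            "g_below",
            "g_above",
            "smoothing",
        ],
    )
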