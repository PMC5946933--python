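"""Burst grouping, activity measures, and infestation thresholding.

Insect sounds in grain arrive as bursts: trains of at least three
profile-matched impulses whose consecutive gaps are under 200 ms. Three
activity measures summarize an analyzed segment:

* ``rb``   - mean burst rate, bursts/s
* ``nb``   - mean impulses per burst (undefined when no bursts occurred)
* ``rbimp`` - rate of impulses counted only within bursts, impulses/s

A segment whose burst rate reaches 0.02 bursts/s is flagged as likely
infested; a sustained fall below that rate marks quiescence, the proxy for
cessation of economically damaging activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "Burst",
    "ActivityMeasures",
    "group_bursts",
    "activity_measures",
    "infestation_flag",
    "time_to_quiescence",
    "DETECTION_THRESHOLD",
    "MAX_INTRA_BURST_GAP",
    "MIN_IMPULSES_PER_BURST",
]

#: Burst rate (bursts/s) below which a sample is treated as having low
#: likelihood of infestation.
DETECTION_THRESHOLD = 0.02

#: Impulses separated by gaps under 200 ms belong to the same train.
MAX_INTRA_BURST_GAP = 0.2

#: A train needs at least three matched impulses to count as a burst.
MIN_IMPULSES_PER_BURST = 3


@dataclass(frozen=True)
class Burst:
    """A train of >= 3 matched impulses with consecutive gaps < 200 ms."""

    start: float
    end: float
    impulse_count: int

    def __post_init__(self) -> None:
        if self.impulse_count < MIN_IMPULSES_PER_BURST:
            raise ValueError("a burst has at least three impulses")
        if self.end < self.start:
            raise ValueError("burst end precedes its start")


@dataclass(frozen=True)
class ActivityMeasures:
    """Per-segment activity summary; ``nb`` is NaN when no bursts occurred."""

    rb: float
    nb: float
    rbimp: float
    duration: float
    n_bursts: int


def group_bursts(
    onsets: Sequence[float],
    max_gap: float = MAX_INTRA_BURST_GAP,
    min_count: int = MIN_IMPULSES_PER_BURST,
) -> list[Burst]:
    """Group sorted insect-impulse onsets into bursts.

    Maximal runs in which every consecutive gap is strictly below
    ``max_gap`` become bursts when they contain at least ``min_count``
    impulses; shorter runs are discarded. A gap of exactly ``max_gap``
    splits the run (the criterion is strict).
    """
    onsets = list(onsets)
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("onsets must be sorted ascending")
    bursts: list[Burst] = []
    run_start = 0
    for i in range(1, len(onsets) + 1):
        if i == len(onsets) or onsets[i] - onsets[i - 1] >= max_gap:
            run = onsets[run_start:i]
            if len(run) >= min_count:
                bursts.append(Burst(start=run[0], end=run[-1], impulse_count=len(run)))
            run_start = i
    return bursts


def activity_measures(bursts: Sequence[Burst], duration: float) -> ActivityMeasures:
    """Compute rb, nb and rbimp for a segment of known duration (s).

    ``nb`` is reported as NaN (missing, never zero) when the segment holds
    no bursts, so that downstream regressions drop rather than bias on it.
    """
    if not duration > 0:
        raise ValueError(f"segment duration must be positive, got {duration}")
    n_bursts = len(bursts)
    total_impulses = sum(b.impulse_count for b in bursts)
    rb = n_bursts / duration
    rbimp = total_impulses / duration
    nb = total_impulses / n_bursts if n_bursts else math.nan
    return ActivityMeasures(rb=rb, nb=nb, rbimp=rbimp,
                            duration=duration, n_bursts=n_bursts)


def infestation_flag(rb: float, threshold: float = DETECTION_THRESHOLD) -> bool:
    """True when the burst rate reaches the detection threshold.

    The boundary is inclusive: a rate of exactly 0.02 bursts/s is the
    minimum rate at which infestation is considered likely.
    """
    if rb < 0:
        raise ValueError(f"burst rate cannot be negative, got {rb}")
    return rb >= threshold


def time_to_quiescence(
    series: Sequence[tuple[float, float]],
    threshold: float = DETECTION_THRESHOLD,
) -> float | None:
    """First day of a sustained fall of burst rate below the threshold.

    Returns the earliest observed day ``d`` such that the rate is below
    ``threshold`` at ``d`` and at every later observed day; day-to-day
    activity is non-monotone, so a single sub-threshold reading does not
    qualify unless it is the last. Returns ``None`` when activity never
    stays below the threshold.
    """
    series = list(series)
    if not series:
        raise ValueError("empty burst-rate series")
    days = [d for d, _ in series]
    if any(b < a for a, b in zip(days, days[1:])):
        raise ValueError("days must be ascending")
    quiescent_from = None
    for day, rb in reversed(series):
        if rb < threshold:
            quiescent_from = day
        else:
            break
    return quiescent_from
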