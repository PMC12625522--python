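"""Physical-activity-pattern metrics from epoch label sequences.

Three outcome families, all expressed as daily means over a participant's
valid days:

* time use — minutes per day spent walking, standing, sitting, lying;
* bout histograms — counts of maximal same-label runs, binned by duration
  (narrow bins for the short upright activities, broad bins for the long
  sedentary ones);
* sedentary-to-active transitions — adjacent-epoch changes from sitting or
  lying directly to standing or walking (exactly four ordered pairs).

Bout bins use the half-open convention [lo, hi): a bout of exactly 2.0 min
falls in the "2-3 min" bin. With 60-s epochs every duration is a whole number
of minutes, so the half-open bins partition all observable durations uniquely.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .epochs import (
    ACTIVE_LABELS,
    ANALYSIS_LABELS,
    GAP,
    ActivityLabel,
    ValidSegment,
)

logger = logging.getLogger("actipat")

__all__ = [
    "WALK_STAND_EDGES",
    "SIT_LIE_EDGES",
    "COUNTED_TRANSITION_PAIRS",
    "DailyTimeUse",
    "Bout",
    "BoutHistogram",
    "TransitionSummary",
    "ActivitySummary",
    "time_use",
    "percent_sedentary",
    "detect_bouts",
    "bin_bouts",
    "count_transitions",
    "summarize_participant",
    "summaries_to_frame",
]

#: Bout-duration bin edges in minutes (half-open [lo, hi); last bin open-ended).
WALK_STAND_EDGES: tuple[float, ...] = (1.0, 2.0, 3.0, 10.0, 30.0, math.inf)
SIT_LIE_EDGES: tuple[float, ...] = (1.0, 5.0, 10.0, 30.0, 60.0, math.inf)

_EDGES_BY_ACTIVITY: dict[ActivityLabel, tuple[float, ...]] = {
    ActivityLabel.WALKING: WALK_STAND_EDGES,
    ActivityLabel.STANDING: WALK_STAND_EDGES,
    ActivityLabel.SITTING: SIT_LIE_EDGES,
    ActivityLabel.LYING: SIT_LIE_EDGES,
}

#: The four sedentary-to-active ordered pairs that count as transitions.
COUNTED_TRANSITION_PAIRS: tuple[tuple[ActivityLabel, ActivityLabel], ...] = (
    (ActivityLabel.LYING, ActivityLabel.STANDING),
    (ActivityLabel.LYING, ActivityLabel.WALKING),
    (ActivityLabel.SITTING, ActivityLabel.STANDING),
    (ActivityLabel.SITTING, ActivityLabel.WALKING),
)


def bin_labels(edges: Sequence[float]) -> list[str]:
    """Human-readable bin names, e.g. ``'1-2'`` ... ``'>30'`` (minutes)."""
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if math.isinf(hi):
            out.append(f">{lo:g}")
        else:
            out.append(f"{lo:g}-{hi:g}")
    return out


@dataclass(frozen=True)
class DailyTimeUse:
    """Mean minutes per day in each activity (sums to 1440 on full days)."""

    minutes_walking: float
    minutes_standing: float
    minutes_sitting: float
    minutes_lying: float

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "minutes_walking": self.minutes_walking,
            "minutes_standing": self.minutes_standing,
            "minutes_sitting": self.minutes_sitting,
            "minutes_lying": self.minutes_lying,
        }

    @property
    def total(self) -> float:
        return sum(self.as_dict().values())


@dataclass(frozen=True, slots=True)
class Bout:
    """A maximal run of consecutive epochs with one activity label."""

    activity: ActivityLabel
    start_epoch: int
    duration_minutes: float


@dataclass(frozen=True)
class BoutHistogram:
    """Daily-mean bout counts for one activity across its duration bins."""

    activity: ActivityLabel
    bin_edges: tuple[float, ...]
    daily_mean_counts: np.ndarray

    @property
    def labels(self) -> list[str]:
        return bin_labels(self.bin_edges)


@dataclass(frozen=True)
class TransitionSummary:
    """Sedentary-to-active transition counts over a participant's valid days."""

    per_pair_counts: dict[tuple[ActivityLabel, ActivityLabel], int]
    n_valid_days: int = 1

    @property
    def total(self) -> int:
        return sum(self.per_pair_counts.values())

    @property
    def daily_mean_transitions(self) -> float:
        return self.total / self.n_valid_days


@dataclass(frozen=True)
class ActivitySummary:
    """All pattern metrics for one participant — the analysis exposure row."""

    participant_id: str
    n_valid_days: int
    time_use: DailyTimeUse
    bout_histograms: dict[ActivityLabel, BoutHistogram]
    transitions: TransitionSummary

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {
            "participant_id": self.participant_id,
            "n_valid_days": self.n_valid_days,
            "walking_min": self.time_use.minutes_walking,
            "standing_min": self.time_use.minutes_standing,
            "sitting_min": self.time_use.minutes_sitting,
            "lying_min": self.time_use.minutes_lying,
            "transitions_per_day": self.transitions.daily_mean_transitions,
        }
        for act, hist in self.bout_histograms.items():
            for lab, cnt in zip(hist.labels, hist.daily_mean_counts):
                key = f"{act.name.lower()}_bouts_{lab.replace('-', '_').replace('>', 'gt')}"
                row[key] = float(cnt)
        return row


def time_use(
    day_windows: Sequence[np.ndarray], epoch_seconds: int = 60
) -> DailyTimeUse:
    """Mean minutes per day in each activity over full 24-h windows."""
    if len(day_windows) == 0:
        raise ValueError("time_use needs at least one day window")
    minute = epoch_seconds / 60.0
    counts = np.zeros(4)
    for win in day_windows:
        arr = np.asarray(win)
        if np.any(arr == GAP) or np.any(arr > int(ActivityLabel.LYING)):
            raise ValueError("day windows must contain analysis labels only")
        counts += np.bincount(arr, minlength=4)[:4]
    mins = counts * minute / len(day_windows)
    return DailyTimeUse(*mins)


def percent_sedentary(tu: DailyTimeUse, day_minutes: float = 1440.0) -> float:
    """Percent of the 24-h day spent sitting or lying."""
    return 100.0 * (tu.minutes_sitting + tu.minutes_lying) / day_minutes


def detect_bouts(labels: np.ndarray, epoch_minutes: float = 1.0) -> list[Bout]:
    """Run-length encode a label sequence into maximal same-activity bouts.

    Every epoch belongs to exactly one bout; sequence boundaries terminate
    bouts. The input must be gap-free analysis labels (bouts are defined per
    contiguous segment).
    """
    arr = np.asarray(labels)
    if arr.size == 0:
        return []
    if np.any(arr == GAP):
        raise ValueError("gap marker inside input: detect bouts per contiguous segment")
    if np.any((arr < 0) | (arr > int(ActivityLabel.LYING))):
        raise ValueError("detect_bouts expects analysis labels only")
    change = np.flatnonzero(np.diff(arr) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [arr.size]])
    return [
        Bout(ActivityLabel(int(arr[s])), int(s), float((e - s) * epoch_minutes))
        for s, e in zip(starts, ends)
    ]


def bin_bouts(
    bouts: Iterable[Bout], n_valid_days: int
) -> dict[ActivityLabel, BoutHistogram]:
    """Bin bouts by duration per activity; counts are daily means.

    Bins are half-open ``[lo, hi)``. Bouts shorter than the 1-min bin floor
    (possible only with sub-minute epochs) are excluded and logged.
    """
    if n_valid_days < 1:
        raise ValueError("n_valid_days must be >= 1")
    counts = {act: np.zeros(len(edges) - 1) for act, edges in _EDGES_BY_ACTIVITY.items()}
    n_subminute = 0
    for b in bouts:
        edges = _EDGES_BY_ACTIVITY.get(b.activity)
        if edges is None:
            raise ValueError(f"no bin scheme for activity {b.activity!r}")
        if b.duration_minutes < edges[0]:
            n_subminute += 1
            continue
        # half-open [lo, hi): duration == lo lands in the bin starting at lo
        idx = int(np.searchsorted(edges, b.duration_minutes, side="right")) - 1
        counts[b.activity][idx] += 1
    if n_subminute:
        logger.info("%d sub-minute bout(s) below the 1-min bin floor excluded", n_subminute)
    return {
        act: BoutHistogram(act, _EDGES_BY_ACTIVITY[act], counts[act] / n_valid_days)
        for act in counts
    }


def count_transitions(labels: np.ndarray, n_valid_days: int = 1) -> TransitionSummary:
    """Count adjacent-epoch sedentary-to-active transitions.

    Only the four ordered pairs lying->standing, lying->walking,
    sitting->standing and sitting->walking contribute; every other adjacent
    pair (including lying->sitting and standing->walking) is ignored.
    """
    arr = np.asarray(labels)
    if np.any((arr < 0) | (arr > int(ActivityLabel.LYING))):
        raise ValueError("count_transitions expects analysis labels only")
    a, b = arr[:-1], arr[1:]
    per_pair = {
        pair: int(np.count_nonzero((a == int(pair[0])) & (b == int(pair[1]))))
        for pair in COUNTED_TRANSITION_PAIRS
    }
    return TransitionSummary(per_pair_counts=per_pair, n_valid_days=n_valid_days)


def summarize_participant(
    segment: ValidSegment, epoch_seconds: int | None = None
) -> ActivitySummary:
    """Bundle time-use, bout histograms and transitions for one participant.

    Daily means are taken over the segment's full 24-h windows. Bouts are
    detected on the whole contiguous segment so a bout running across the last
    day boundary keeps its full duration and is attributed to the window in
    which it starts; bouts starting in the trailing remainder (beyond the last
    full day) are not counted. Transitions are counted over pairs whose first
    epoch lies within the full-day span.
    """
    from .epochs import split_days  # local import to avoid cycle at module load

    eps = epoch_seconds or segment.series.epoch_seconds
    minute = eps / 60.0
    windows = split_days(segment)
    tu = time_use(windows, epoch_seconds=eps)
    span = segment.n_valid_days * segment.series.epochs_per_day
    all_bouts = detect_bouts(segment.labels, epoch_minutes=minute)
    counted = [b for b in all_bouts if b.start_epoch < span]
    hists = bin_bouts(counted, segment.n_valid_days)
    # include the pair crossing the last-day cut (it starts inside the span)
    tail = min(len(segment.labels), span + 1)
    trans = count_transitions(segment.labels[:tail], n_valid_days=segment.n_valid_days)
    return ActivitySummary(
        participant_id=segment.participant_id,
        n_valid_days=segment.n_valid_days,
        time_use=tu,
        bout_histograms=hists,
        transitions=trans,
    )


def summaries_to_frame(summaries: Iterable[ActivitySummary]) -> pd.DataFrame:
    """One row per participant: time use, bout-bin daily means, transitions."""
    return pd.DataFrame([s.to_row() for s in summaries])
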