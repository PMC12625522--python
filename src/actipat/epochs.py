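"""Epoch-level activity-label series: reading, validation, remapping, day splitting.

The unit of raw data is a 60-second epoch carrying one activity label produced
by a body-worn-sensor activity classifier. Analysis uses four posture/activity
states (walking, standing, sitting, lying); raw input may additionally contain
``running`` and ``cycling``, which are remapped onto the analysis states before
any metric is computed. A participant contributes to analysis only if their
record contains at least 24 consecutive hours of labelled epochs — a span that
by construction covers both day-time and night-time clock hours.

Gaps in a record (missing epochs between two timestamps) are kept explicit with
a ``GAP`` marker and are never bridged or imputed: a gap terminates the run of
analysable epochs on either side.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("actipat")

__all__ = [
    "ActivityLabel",
    "GAP",
    "ANALYSIS_LABELS",
    "SEDENTARY_LABELS",
    "ACTIVE_LABELS",
    "DEFAULT_REMAP",
    "EpochSeries",
    "ValidSegment",
    "EpochFormatError",
    "EpochDataError",
    "ExclusionError",
    "read_epoch_csv",
    "write_epoch_csv",
    "remap_labels",
    "find_valid_segment",
    "split_days",
]


class ActivityLabel(enum.IntEnum):
    """Activity/posture states. The first four are the analysis labels."""

    WALKING = 0
    STANDING = 1
    SITTING = 2
    LYING = 3
    # raw classifier output only; remapped away before analysis
    RUNNING = 4
    CYCLING = 5

    @property
    def is_analysis(self) -> bool:
        return self.value <= ActivityLabel.LYING.value

    @property
    def is_sedentary(self) -> bool:
        return self in (ActivityLabel.SITTING, ActivityLabel.LYING)

    @property
    def is_active(self) -> bool:
        return self in (ActivityLabel.WALKING, ActivityLabel.STANDING)


#: Sentinel code for a missing epoch inside a series. Never a valid label.
GAP: int = -1

ANALYSIS_LABELS: tuple[ActivityLabel, ...] = (
    ActivityLabel.WALKING,
    ActivityLabel.STANDING,
    ActivityLabel.SITTING,
    ActivityLabel.LYING,
)
SEDENTARY_LABELS = frozenset({ActivityLabel.SITTING, ActivityLabel.LYING})
ACTIVE_LABELS = frozenset({ActivityLabel.WALKING, ActivityLabel.STANDING})

#: Default raw->analysis remapping. Cycling calls are walking-with-a-walker
#: misclassifications; running is included for completeness (it does not occur
#: in faithful data) so the remap is total on the raw label set.
DEFAULT_REMAP: dict[ActivityLabel, ActivityLabel] = {
    ActivityLabel.CYCLING: ActivityLabel.WALKING,
    ActivityLabel.RUNNING: ActivityLabel.WALKING,
}

_STR_TO_CODE = {lab.name.lower(): int(lab) for lab in ActivityLabel}
_CODE_TO_STR = {int(lab): lab.name.lower() for lab in ActivityLabel}

REQUIRED_COLUMNS = ("participant_id", "timestamp", "label")


class EpochFormatError(ValueError):
    """The input file does not have the expected structure."""


class EpochDataError(ValueError):
    """The input file is well-formed but its content is inconsistent."""


class ExclusionError(RuntimeError):
    """The participant does not meet the 24-h consecutive wear criterion."""


@dataclass(frozen=True)
class EpochSeries:
    """One participant's contiguous-grid sequence of epoch labels.

    ``labels`` is an int8 array of :class:`ActivityLabel` codes, with ``GAP``
    (-1) marking missing epochs. The grid is uniform: epoch ``i`` starts at
    ``start_time + i * epoch_seconds``.
    """

    participant_id: str
    start_time: pd.Timestamp
    labels: np.ndarray = field(repr=False)
    epoch_seconds: int = 60

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels, dtype=np.int8)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("EpochSeries needs a 1-d label sequence of length >= 1")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        object.__setattr__(self, "labels", arr)

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def epochs_per_day(self) -> int:
        return 86400 // self.epoch_seconds

    @property
    def has_gap(self) -> bool:
        return bool(np.any(self.labels == GAP))

    @property
    def is_analysis_only(self) -> bool:
        """True when every epoch carries one of the four analysis labels."""
        return bool(
            np.all((self.labels >= 0) & (self.labels <= int(ActivityLabel.LYING)))
        )

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=len(self), freq=f"{self.epoch_seconds}s"
        )


@dataclass(frozen=True)
class ValidSegment:
    """A gap-free span of at least 24 consecutive hours for one participant."""

    series: EpochSeries
    n_valid_days: int

    def __post_init__(self) -> None:
        if self.n_valid_days < 1:
            raise ValueError("a valid segment spans at least one day")
        if self.series.has_gap:
            raise ValueError("a valid segment must be gap-free")

    @property
    def participant_id(self) -> str:
        return self.series.participant_id

    @property
    def labels(self) -> np.ndarray:
        return self.series.labels


def _parse_labels(raw: pd.Series, path: object) -> np.ndarray:
    codes = raw.str.strip().str.lower().map(_STR_TO_CODE)
    if codes.isna().any():
        bad = raw[codes.isna()].iloc[0]
        raise EpochDataError(f"{path}: unknown activity label {bad!r}")
    return codes.to_numpy(dtype=np.int8)


def read_epoch_csv(
    path, epoch_seconds: int = 60, *, max_gap_epochs: int | None = None
) -> list[EpochSeries]:
    """Read a per-epoch label CSV into one :class:`EpochSeries` per participant.

    The file has columns ``participant_id,timestamp,label`` with ISO-8601
    timestamps and lowercase labels. Within a participant, rows must be
    strictly increasing in time on the ``epoch_seconds`` grid; missing epochs
    become explicit ``GAP`` markers. Duplicate or out-of-order timestamps and
    off-grid spacings are data errors, reported with the offending row index.

    Parameters
    ----------
    max_gap_epochs
        If given, refuse files whose largest internal gap exceeds this many
        epochs (guards against accidentally concatenated recordings).
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise EpochFormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: no epoch rows (header only)", path)
        return []
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise EpochFormatError(f"{path}: unparseable timestamp ({exc})") from exc

    out: list[EpochSeries] = []
    for pid, grp in df.groupby("participant_id", sort=True):
        ts = grp["timestamp"].to_numpy()
        steps = np.diff(ts).astype("timedelta64[s]").astype(np.int64)
        bad = np.flatnonzero(steps <= 0)
        if bad.size:
            row = grp.index[bad[0] + 1]
            kind = "duplicate" if steps[bad[0]] == 0 else "non-monotone"
            raise EpochDataError(
                f"{path}: {kind} timestamp for participant {pid} at row {row}"
            )
        if np.any(steps % epoch_seconds != 0):
            row = grp.index[int(np.flatnonzero(steps % epoch_seconds)[0]) + 1]
            raise EpochDataError(
                f"{path}: timestamp off the {epoch_seconds}-s grid for "
                f"participant {pid} at row {row}"
            )
        n_slots = int((ts[-1] - ts[0]) / np.timedelta64(epoch_seconds, "s")) + 1
        labels = np.full(n_slots, GAP, dtype=np.int8)
        idx = ((ts - ts[0]) / np.timedelta64(epoch_seconds, "s")).astype(np.int64)
        labels[idx] = _parse_labels(grp["label"], path)
        n_gap = n_slots - len(grp)
        if n_gap:
            if max_gap_epochs is not None:
                runs = _gap_run_lengths(labels)
                if runs and max(runs) > max_gap_epochs:
                    raise EpochDataError(
                        f"{path}: participant {pid} has a gap of {max(runs)} "
                        f"epochs (> {max_gap_epochs})"
                    )
            logger.info(
                "participant %s: %d missing epoch(s) marked as gaps", pid, n_gap
            )
        out.append(
            EpochSeries(
                participant_id=str(pid),
                start_time=pd.Timestamp(ts[0]),
                labels=labels,
                epoch_seconds=epoch_seconds,
            )
        )
    return out


def _gap_run_lengths(labels: np.ndarray) -> list[int]:
    is_gap = labels == GAP
    if not is_gap.any():
        return []
    padded = np.concatenate([[False], is_gap, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(edges[1::2] - edges[0::2])


def write_epoch_csv(series: Iterable[EpochSeries], path) -> None:
    """Write series back to the epoch CSV format. Gap epochs emit no row."""
    frames = []
    for s in series:
        keep = s.labels != GAP
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "timestamp": s.timestamps()[keep].strftime("%Y-%m-%dT%H:%M:%S"),
                    "label": [_CODE_TO_STR[int(c)] for c in s.labels[keep]],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def remap_labels(
    series: EpochSeries,
    mapping: Mapping[ActivityLabel, ActivityLabel] | None = None,
) -> EpochSeries:
    """Map raw classifier labels onto the four analysis labels.

    By default cycling and running become walking (cycling calls in this
    population are walker-assisted walking; running does not occur). The number
    of remapped epochs is logged as provenance. Labels that are neither
    analysis labels nor mapping keys raise :class:`EpochDataError`.
    """
    if mapping is None:
        mapping = DEFAULT_REMAP
    labels = series.labels.copy()
    n_remapped = 0
    raw_present = np.unique(labels[labels > int(ActivityLabel.LYING)])
    for code in raw_present:
        lab = ActivityLabel(int(code))
        if lab not in mapping:
            raise EpochDataError(
                f"participant {series.participant_id}: raw label {lab.name} "
                "has no remap rule"
            )
        target = mapping[lab]
        if not ActivityLabel(target).is_analysis:
            raise EpochDataError(f"remap target {target!r} is not an analysis label")
        mask = labels == int(code)
        labels[mask] = int(target)
        n_remapped += int(mask.sum())
    if n_remapped:
        logger.info(
            "participant %s: remapped %d epoch(s) onto analysis labels",
            series.participant_id,
            n_remapped,
        )
        return replace(series, labels=labels)
    return series


def find_valid_segment(series: EpochSeries, min_hours: float = 24.0) -> ValidSegment:
    """Extract the longest gap-free run if it spans at least ``min_hours``.

    Returns the longest maximal run of consecutive non-gap epochs (earliest
    wins ties) as a :class:`ValidSegment` with ``n_valid_days = floor(run /
    epochs-per-day)``. Raises :class:`ExclusionError` when no run is long
    enough — the participant is excluded from analysis, mirroring the study's
    24-consecutive-hour wear requirement.
    """
    if 3600 % series.epoch_seconds != 0:
        raise ValueError("epoch_seconds must divide 3600")
    need = int(round(min_hours * 3600 / series.epoch_seconds))
    ok = series.labels != GAP
    padded = np.concatenate([[False], ok, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]
    if starts.size == 0:
        raise ExclusionError(
            f"participant {series.participant_id}: no labelled epochs"
        )
    lengths = stops - starts
    best = int(np.argmax(lengths))  # argmax -> earliest maximal run
    if lengths[best] < need:
        raise ExclusionError(
            f"participant {series.participant_id}: longest consecutive run is "
            f"{lengths[best]} epochs (< {need} needed for {min_hours} h); excluded"
        )
    start, stop = int(starts[best]), int(stops[best])
    sub = EpochSeries(
        participant_id=series.participant_id,
        start_time=series.start_time + pd.Timedelta(seconds=start * series.epoch_seconds),
        labels=series.labels[start:stop],
        epoch_seconds=series.epoch_seconds,
    )
    return ValidSegment(series=sub, n_valid_days=int(lengths[best] // series.epochs_per_day))


def split_days(segment: ValidSegment) -> list[np.ndarray]:
    """Cut a valid segment into consecutive 24-h label windows.

    Windows are anchored at the segment's first epoch (a rolling 24-h day, not
    a calendar day). A trailing remainder shorter than one day is discarded
    from daily means, with a warning; bouts crossing the final cut are handled
    by the metrics layer.
    """
    per_day = segment.series.epochs_per_day
    labels = segment.labels
    k = segment.n_valid_days
    remainder = len(labels) - k * per_day
    if remainder:
        logger.warning(
            "participant %s: %d trailing epoch(s) beyond the last full day "
            "are excluded from daily means",
            segment.participant_id,
            remainder,
        )
    return [labels[i * per_day : (i + 1) * per_day] for i in range(k)]
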