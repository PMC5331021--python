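"""Reading, writing and windowing of minute-epoch actigraphy recordings.

A recording is a sequence of non-negative integer activity counts, one per
minute, with a start timestamp — the 1-min epoch export of a wrist-worn
actigraph. Analysis operates on two day windows: the morning
(06:00–15:00) and the evening (15:00–24:00); windows are half-open, so
15:00 belongs to the evening only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

__all__ = [
    "MinuteSeries",
    "DayWindow",
    "MORNING",
    "EVENING",
    "read_minute_series",
    "write_minute_series",
    "slice_window",
]

MINUTES_PER_DAY = 1440

DaySelection = Literal["prefer_maximal_coverage", "first", "second"]


@dataclass(frozen=True)
class MinuteSeries:
    """One subject's minute-by-minute activity counts.

    Counts are stored as a contiguous int64 array covering consecutive
    minutes from ``start_time``; gaps are a hard error upstream, never
    represented here.
    """

    subject_id: str
    start_time: pd.Timestamp
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1:
            raise IntegrityError(f"{self.subject_id}: counts must be 1-D")
        if counts.size and counts.min() < 0:
            raise IntegrityError(f"{self.subject_id}: negative activity count")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "start_time", pd.Timestamp(self.start_time).floor("min"))

    def __len__(self) -> int:
        return self.counts.size

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self), freq="min")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "timestamp": self.times,
                "activity_count": self.counts,
            }
        )


@dataclass(frozen=True)
class DayWindow:
    """Half-open clock-time window [start, end) given in minutes of day."""

    label: str
    start_minute: int
    end_minute: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_minute < self.end_minute <= MINUTES_PER_DAY):
            raise ValueError(f"invalid window bounds {self.start_minute}..{self.end_minute}")

    def contains(self, minute_of_day: np.ndarray) -> np.ndarray:
        return (minute_of_day >= self.start_minute) & (minute_of_day < self.end_minute)


#: Morning window, 06:00 to 15:00.
MORNING = DayWindow("morning", 6 * 60, 15 * 60)
#: Evening window, 15:00 to midnight.
EVENING = DayWindow("evening", 15 * 60, 24 * 60)

_REQUIRED_COLUMNS = ("subject_id", "timestamp", "activity_count")


def read_minute_series(path) -> list[MinuteSeries]:
    """Read a cohort CSV (subject_id, timestamp, activity_count) into one
    :class:`MinuteSeries` per subject.

    Rows are sorted by time within subject; timestamps must form one
    unbroken run of consecutive minutes per subject.

    Raises
    ------
    FormatError
        if a required column is missing.
    IntegrityError
        on a duplicated or missing minute, or a negative count.
    """
    frame = pd.read_csv(path)
    for column in _REQUIRED_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"missing required column {column!r} in {path}")
    frame = frame.copy()
    frame["timestamp"] = pd.to_datetime(frame["timestamp"]).dt.floor("min")

    out: list[MinuteSeries] = []
    for subject_id, rows in frame.groupby("subject_id", sort=True):
        rows = rows.sort_values("timestamp")
        times = rows["timestamp"].to_numpy()
        steps = np.diff(times).astype("timedelta64[s]").astype(np.int64)
        if np.any(steps == 0):
            where = pd.Timestamp(times[np.argmax(steps == 0) + 1])
            raise IntegrityError(f"duplicate timestamp for subject {subject_id} at {where}")
        if np.any(steps != 60):
            where = pd.Timestamp(times[int(np.argmax(steps != 60))])
            raise IntegrityError(f"gap in recording for subject {subject_id} after {where}")
        counts = rows["activity_count"].to_numpy()
        if np.any(counts < 0):
            raise IntegrityError(f"negative activity count for subject {subject_id}")
        out.append(MinuteSeries(str(subject_id), pd.Timestamp(times[0]), counts))
    return out


def write_minute_series(series: Iterable[MinuteSeries], path) -> None:
    """Write one or more minute series to a cohort CSV (ISO-8601 minute
    timestamps, integer counts)."""
    frames = [s.to_frame() for s in series]
    table = pd.concat(frames, ignore_index=True)
    table["timestamp"] = table["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
    table.to_csv(path, index=False)


def _contiguous_blocks(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of the True runs in a boolean mask."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def slice_window(
    series: MinuteSeries,
    window: DayWindow,
    day_selection: DaySelection = "prefer_maximal_coverage",
) -> MinuteSeries:
    """Extract the sub-series whose clock times fall inside ``window``.

    A ~22-h recording that starts mid-day can cover the same clock window
    on two calendar days; ``day_selection`` picks which instance:

    - ``prefer_maximal_coverage`` (default): the instance with more
      recorded minutes, ties to the earlier day;
    - ``first`` / ``second``: that calendar-day instance unconditionally.

    Returns an empty series (length 0) when the window has no coverage.
    The output is always a verbatim contiguous slice of the input.
    """
    if len(series) == 0:
        return series
    start = series.start_time
    minute_of_day = (
        np.arange(len(series)) + start.hour * 60 + start.minute
    ) % MINUTES_PER_DAY
    blocks = _contiguous_blocks(window.contains(minute_of_day))
    if not blocks:
        return MinuteSeries(series.subject_id, start, np.empty(0, dtype=np.int64))
    if day_selection == "first":
        lo, hi = blocks[0]
    elif day_selection == "second":
        if len(blocks) < 2:
            return MinuteSeries(series.subject_id, start, np.empty(0, dtype=np.int64))
        lo, hi = blocks[1]
    elif day_selection == "prefer_maximal_coverage":
        lo, hi = max(blocks, key=lambda b: (b[1] - b[0], -b[0]))
    else:
        raise ValueError(f"unknown day_selection {day_selection!r}")
    return MinuteSeries(
        series.subject_id,
        start + pd.Timedelta(minutes=lo),
        series.counts[lo:hi],
    )
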