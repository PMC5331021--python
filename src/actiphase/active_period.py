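"""Search for the 64-min continuous active period in a day window.

A segment qualifies at zero-run tolerance ``k`` when it contains no run of
more than ``k`` consecutive zero-count minutes. The search starts at
tolerance 2 and relaxes it one minute at a time until some 64-min window
qualifies: morning segments are searched forward from the start of the
window, evening segments backward from its end (i.e. the latest-starting
qualifying window is returned). Tolerance escalates globally: every start
position is tried at tolerance ``k`` before any is tried at ``k+1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .actigraphy_io import MinuteSeries
from .errors import InsufficientDataError

__all__ = ["ActiveSegment", "max_zero_run", "find_active_segment", "SEGMENT_LENGTH"]

#: Power-of-two segment length (minutes) required by the spectral analysis.
SEGMENT_LENGTH = 64

Direction = Literal["forward", "backward"]


@dataclass(frozen=True)
class ActiveSegment:
    """A qualifying 64-min slice of a day window."""

    subject_id: str
    window_label: str
    start_time: pd.Timestamp
    counts: np.ndarray = field(repr=False)
    tolerance_used: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)


def max_zero_run(counts) -> int:
    """Length of the longest run of consecutive zeros (0 if none).

    Raises ``ValueError`` on empty input.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("max_zero_run of an empty sequence")
    is_zero = np.concatenate(([0], (counts == 0).astype(np.int8), [0]))
    edges = np.flatnonzero(np.diff(is_zero))
    if edges.size == 0:
        return 0
    return int((edges[1::2] - edges[::2]).max())


def _zero_run_ending_at(counts: np.ndarray) -> np.ndarray:
    """For each index t, the length of the zero run ending at t."""
    out = np.zeros(counts.size, dtype=np.int64)
    run = 0
    for t, value in enumerate(counts):
        run = run + 1 if value == 0 else 0
        out[t] = run
    return out


def find_active_segment(
    window_series: MinuteSeries,
    direction: Direction,
    window_label: str | None = None,
    length: int = SEGMENT_LENGTH,
    start_tolerance: int = 2,
) -> ActiveSegment:
    """Locate the first qualifying ``length``-minute segment.

    For tolerance k = start_tolerance, start_tolerance+1, …, slide a
    ``length``-min window in 1-min steps — ascending start positions when
    ``direction="forward"``, descending when ``"backward"`` — and return
    the first window whose longest zero run is ≤ k, tagged with that k.
    A tolerance of ``length`` always qualifies, so the search terminates.

    Raises
    ------
    InsufficientDataError
        if the window is shorter than ``length`` minutes.
    """
    counts = window_series.counts
    n = counts.size
    label = window_label if window_label is not None else direction
    if n < length:
        raise InsufficientDataError(
            f"subject {window_series.subject_id}, window {label}: "
            f"{n} min available, {length} required"
        )
    run_ending = _zero_run_ending_at(counts)
    n_starts = n - length + 1
    # longest zero run fully visible inside window [s, s+length)
    window_max = np.empty(n_starts, dtype=np.int64)
    for s in range(n_starts):
        tail = run_ending[s : s + length]
        clipped = np.minimum(tail, np.arange(1, length + 1))
        window_max[s] = clipped.max()

    starts = range(n_starts) if direction == "forward" else range(n_starts - 1, -1, -1)
    for k in range(start_tolerance, length + 1):
        for s in starts:
            if window_max[s] <= k:
                return ActiveSegment(
                    subject_id=window_series.subject_id,
                    window_label=label,
                    start_time=window_series.start_time + pd.Timedelta(minutes=s),
                    counts=counts[s : s + length].copy(),
                    tolerance_used=k,
                )
    raise AssertionError("unreachable: tolerance == length always qualifies")
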