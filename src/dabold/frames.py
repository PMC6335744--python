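"""Dynamic PET frame schedules.

A dynamic acquisition is described by a list of frames, each with a start
time and a duration (seconds from tracer injection). Frames are contiguous
and non-overlapping; quantification works on frame mid-times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np

from .exceptions import InvalidSpecError

__all__ = ["FrameSchedule", "make_schedule", "DEFAULT_SCHEDULE_SPEC"]

#: Conventional 55-minute 18-frame raclopride schedule:
#: nine 120 s frames, then three each of 180, 260 and 300 s.
DEFAULT_SCHEDULE_SPEC: Tuple[Tuple[int, float], ...] = (
    (9, 120.0),
    (3, 180.0),
    (3, 260.0),
    (3, 300.0),
)


@dataclass(frozen=True)
class FrameSchedule:
    """Timing of a dynamic PET scan.

    Parameters
    ----------
    frame_starts
        Frame start times in seconds from injection.
    frame_durations
        Frame durations in seconds; all strictly positive.
    """

    frame_starts: np.ndarray
    frame_durations: np.ndarray
    mid_times: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        starts = np.asarray(self.frame_starts, dtype=float)
        durs = np.asarray(self.frame_durations, dtype=float)
        if starts.shape != durs.shape or starts.ndim != 1:
            raise InvalidSpecError("frame starts and durations must be 1-D and equal length")
        if np.any(durs <= 0):
            raise InvalidSpecError("frame durations must be strictly positive")
        ends = starts + durs
        if not np.allclose(starts[1:], ends[:-1]):
            raise InvalidSpecError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "frame_starts", starts)
        object.__setattr__(self, "frame_durations", durs)
        object.__setattr__(self, "mid_times", starts + durs / 2.0)

    @property
    def n_frames(self) -> int:
        return int(self.frame_starts.size)

    @property
    def total_duration(self) -> float:
        """Total scan duration in seconds."""
        return float(self.frame_durations.sum())

    @property
    def frame_ends(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations

    @property
    def mid_times_min(self) -> np.ndarray:
        """Frame mid-times in minutes, the natural unit for kinetic work."""
        return self.mid_times / 60.0

    def __len__(self) -> int:
        return self.n_frames


def make_schedule(spec: Iterable[Sequence[float]]) -> FrameSchedule:
    """Build a contiguous :class:`FrameSchedule` from ``(count, duration_s)`` pairs.

    Frames are laid out from t=0 in the order given. ``make_schedule([])``
    yields an empty zero-duration schedule.

    >>> sched = make_schedule([(9, 120), (3, 180), (3, 260), (3, 300)])
    >>> sched.n_frames, sched.total_duration / 60
    (18, 55.0)
    """
    durations: list[float] = []
    for item in spec:
        count, dur = item
        count = int(count)
        if count < 0:
            raise InvalidSpecError(f"frame count must be >= 0, got {count}")
        if dur <= 0:
            raise InvalidSpecError(f"frame duration must be > 0, got {dur}")
        durations.extend([float(dur)] * count)
    durs = np.asarray(durations, dtype=float)
    starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]]) if durs.size else np.empty(0)
    if durs.size == 0:
        return _empty_schedule()
    return FrameSchedule(starts, durs)


def _empty_schedule() -> FrameSchedule:
    sched = object.__new__(FrameSchedule)
    object.__setattr__(sched, "frame_starts", np.empty(0))
    object.__setattr__(sched, "frame_durations", np.empty(0))
    object.__setattr__(sched, "mid_times", np.empty(0))
    return sched
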