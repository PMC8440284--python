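"""Dynamic PET frame schedules and regional time-activity curves.

A 90-minute [11C]PBR28 acquisition is binned into 26 frames
(8 x 15 s, 3 x 1 min, 5 x 2 min, 5 x 5 min, 5 x 10 min); all activities
are assumed decay-corrected by the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping frame grid in minutes."""

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValueError("frame_start and frame_duration must be 1-D and equal length")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def frame_mid(self) -> np.ndarray:
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def total_duration(self) -> float:
        return float(self.frame_end[-1])

    def __len__(self) -> int:
        return self.frame_start.size


def default_schedule() -> FrameSchedule:
    """The 26-frame, 90-min schedule: 8x15 s, 3x1, 5x2, 5x5, 5x10 min."""
    durations = np.concatenate(
        [
            np.full(8, 0.25),
            np.full(3, 1.0),
            np.full(5, 2.0),
            np.full(5, 5.0),
            np.full(5, 10.0),
        ]
    )
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)


@dataclass
class TAC:
    """A regional time-activity curve on a frame schedule (kBq/mL)."""

    schedule: FrameSchedule
    activity: np.ndarray
    region: str = ""
    condition: str = ""  # "baseline" / "blocking" for blocking-study scans
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.shape != self.schedule.frame_start.shape:
            raise ValueError("activity length must match the frame schedule")
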