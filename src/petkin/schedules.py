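"""Acquisition and blood-sampling schedules.

The study design this package targets is a 60-minute dynamic small-animal
PET acquisition rebinned into 20 frames (9 x 20 s, 4 x 60 s, 4 x 120 s,
3 x 900 s), with 13 arterial blood samples (six in the first minute, seven
out to 50 min) of which four (5, 25, 40, 50 min) carry a measured plasma
parent fraction.  Those schedules are exposed here as constants so that
every module and the synthetic-data generator share one definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "FrameSchedule",
    "default_frame_schedule",
    "default_arterial_times",
    "default_metabolite_times",
    "default_schedules",
    "default_fine_grid",
    "ARTERIAL_SAMPLE_TIMES_MIN",
    "METABOLITE_SAMPLE_TIMES_MIN",
]

#: Arterial sampling times in minutes: 3, 10, 20, 30, 40, 50 s then
#: 1, 2, 5, 10, 25, 40, 50 min post-injection (13 samples).
ARTERIAL_SAMPLE_TIMES_MIN: tuple[float, ...] = (
    3 / 60, 10 / 60, 20 / 60, 30 / 60, 40 / 60, 50 / 60,
    1.0, 2.0, 5.0, 10.0, 25.0, 40.0, 50.0,
)

#: Subset of arterial samples analysed for metabolites (minutes).
METABOLITE_SAMPLE_TIMES_MIN: tuple[float, ...] = (5.0, 25.0, 40.0, 50.0)

#: (count, duration_s) pairs of the default dynamic rebinning.
DEFAULT_FRAMING: tuple[tuple[int, int], ...] = ((9, 20), (4, 60), (4, 120), (3, 900))


@dataclass(frozen=True)
class FrameSchedule:
    """Start/end times of contiguous dynamic PET frames, in seconds."""

    start_s: np.ndarray
    end_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        end = np.asarray(self.end_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "end_s", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise ValidationError("frame starts/ends must be matching 1-D arrays")
        if np.any(np.diff(start) <= 0):
            raise ValidationError("frame start times must be strictly increasing")
        if np.any(end <= start):
            raise ValidationError("each frame end must exceed its start")
        if np.any(end[:-1] > start[1:] + 1e-9):
            raise ValidationError("frames must not overlap")

    @property
    def n_frames(self) -> int:
        return self.start_s.size

    @property
    def duration_s(self) -> np.ndarray:
        return self.end_s - self.start_s

    @property
    def mid_min(self) -> np.ndarray:
        """Frame mid-times in minutes."""
        return (self.start_s + self.end_s) / 2.0 / 60.0

    @property
    def total_duration_s(self) -> float:
        return float(self.end_s[-1] - self.start_s[0])

    @classmethod
    def from_framing(cls, framing=DEFAULT_FRAMING, t0_s: float = 0.0) -> "FrameSchedule":
        durations = np.concatenate([np.full(n, d, dtype=float) for n, d in framing])
        edges = t0_s + np.concatenate([[0.0], np.cumsum(durations)])
        return cls(start_s=edges[:-1], end_s=edges[1:])


def default_frame_schedule() -> FrameSchedule:
    """The 20-frame 60-minute schedule: 9 x 20 s, 4 x 60 s, 4 x 120 s, 3 x 900 s."""
    return FrameSchedule.from_framing()


def default_arterial_times() -> np.ndarray:
    return np.array(ARTERIAL_SAMPLE_TIMES_MIN, dtype=float)


def default_metabolite_times() -> np.ndarray:
    return np.array(METABOLITE_SAMPLE_TIMES_MIN, dtype=float)


def default_schedules() -> tuple[FrameSchedule, np.ndarray, np.ndarray]:
    """Return (frame schedule, arterial sample times, metabolite subset times)."""
    return default_frame_schedule(), default_arterial_times(), default_metabolite_times()


def default_fine_grid(t_end_min: float = 60.0, dt_s: float = 1.0) -> np.ndarray:
    """Uniform fine time grid in minutes (default 1 s spacing on [0, 60] min).

    One-second resolution resolves the 20 s early frames; coarser grids
    are admitted for speed in simulations.
    """
    n = int(round(t_end_min * 60.0 / dt_s))
    return np.linspace(0.0, t_end_min, n + 1)
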