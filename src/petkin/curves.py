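"""In-memory containers for input functions and time-activity curves."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .exceptions import ValidationError
from .schedules import FrameSchedule

__all__ = ["InputFunction", "TimeActivityCurve", "SessionMeta"]

SESSIONS = ("baseline", "D0+6", "D0+35")


@dataclass(frozen=True)
class SessionMeta:
    """Injection metadata for one imaging session.

    dose is the injected activity in MBq; weight the animal's body weight
    in grams.  Both enter the SUV definition and the cross-session input
    function normalization.
    """

    subject: str
    session: str
    dose_MBq: float
    weight_g: float

    def __post_init__(self) -> None:
        if not self.dose_MBq > 0:
            raise ValidationError(f"injected dose must be > 0 MBq, got {self.dose_MBq}")
        if not self.weight_g > 0:
            raise ValidationError(f"body weight must be > 0 g, got {self.weight_g}")

    @property
    def dose_Bq(self) -> float:
        return self.dose_MBq * 1e6


@dataclass(frozen=True)
class InputFunction:
    """Metabolite-corrected plasma parent activity on a fine time grid.

    ``plasma`` is the parent (unmetabolized) tracer concentration in plasma,
    kBq/mL; ``blood`` is the companion whole-blood curve on the same grid.
    ``provenance`` records how the curve was obtained: directly from arterial
    samples ("measured"), by cross-session dose/weight normalization
    ("session-derived"), or from a cohort mean ("mean-derived").
    """

    t_min: np.ndarray
    plasma: np.ndarray
    blood: Optional[np.ndarray] = None
    provenance: str = "measured"
    meta: Optional[SessionMeta] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t_min, dtype=float)
        p = np.asarray(self.plasma, dtype=float)
        object.__setattr__(self, "t_min", t)
        object.__setattr__(self, "plasma", p)
        if self.blood is not None:
            b = np.asarray(self.blood, dtype=float)
            object.__setattr__(self, "blood", b)
            if b.shape != t.shape:
                raise ValidationError("blood curve must share the plasma time grid")
            if not np.all(np.isfinite(b)) or np.any(b < 0):
                raise ValidationError("blood activity must be finite and >= 0")
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValidationError("time grid must be 1-D and strictly increasing")
        if p.shape != t.shape:
            raise ValidationError("plasma curve must match the time grid")
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ValidationError("plasma activity must be finite and >= 0")
        if t[0] == 0.0 and abs(p[0]) > 1e-12:
            raise ValidationError("plasma activity at t = 0 must be 0")
        if self.provenance not in ("measured", "session-derived", "mean-derived"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")

    def plasma_at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the plasma curve (flat beyond the grid)."""
        return np.interp(np.asarray(t, dtype=float), self.t_min, self.plasma)

    def blood_at(self, t: np.ndarray) -> np.ndarray:
        if self.blood is None:
            raise ValidationError("input function has no companion blood curve")
        return np.interp(np.asarray(t, dtype=float), self.t_min, self.blood)

    def resample(self, grid: np.ndarray) -> "InputFunction":
        grid = np.asarray(grid, dtype=float)
        blood = None if self.blood is None else np.interp(grid, self.t_min, self.blood)
        return replace(self, t_min=grid, plasma=self.plasma_at(grid), blood=blood)

    def scaled(self, factor: float, provenance: Optional[str] = None,
               meta: Optional[SessionMeta] = None) -> "InputFunction":
        return InputFunction(
            t_min=self.t_min,
            plasma=self.plasma * factor,
            blood=None if self.blood is None else self.blood * factor,
            provenance=provenance or self.provenance,
            meta=meta if meta is not None else self.meta,
        )

    def plot(self, ax=None, **kwargs):
        """Plot plasma (and blood, if present) against time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t_min, self.plasma, label="plasma parent", **kwargs)
        if self.blood is not None:
            ax.plot(self.t_min, self.blood, label="whole blood", ls="--", **kwargs)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("activity (kBq/mL)")
        ax.legend()
        return ax


@dataclass(frozen=True)
class TimeActivityCurve:
    """One region's decay-corrected activity concentration per frame."""

    subject: str
    session: str
    region: str
    side: str  # "left" / "right" / "unpaired"
    schedule: FrameSchedule
    values: np.ndarray  # kBq/mL, one per frame
    noise_flag: bool = False  # set when a noise model may have produced negatives

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.schedule.n_frames,):
            raise ValidationError(
                f"TAC needs one value per frame ({self.schedule.n_frames}), got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError("TAC values must be finite")
        if np.any(v < 0) and not self.noise_flag:
            raise ValidationError("negative TAC values require noise_flag=True")

    @property
    def mid_min(self) -> np.ndarray:
        return self.schedule.mid_min

    def scaled(self, factor: float) -> "TimeActivityCurve":
        return replace(self, values=self.values * factor)

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.mid_min, self.values, marker="o",
                label=f"{self.region} ({self.side})", **kwargs)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("activity (kBq/mL)")
        return ax
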