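"""Arterial input-function construction, metabolite correction and normalization.

Workflow for a session with arterial sampling:

1. a straight line is fitted to the plasma-over-blood activity ratio of the
   discrete samples (``fit_plasma_over_blood``);
2. the plasma parent fraction — unity up to a *begin* time point, then a
   continuous biexponential decline — is fitted to the metabolite subset
   (``fit_parent_fraction``);
3. the sampled whole-blood curve is interpolated to a fine grid, multiplied
   by the ratio line to give total plasma activity and by the parent
   fraction to give the metabolite-corrected AIF (``build_aif``).

Sessions without arterial sampling receive a *derived* AIF: the measured
AIF of another session of the same subject, rescaled by the scalar implied
by assuming the AIF is invariant in SUV units across sessions
(``normalize_aif_to_session``), or a rescaled cohort mean AIF
(``build_mean_aif``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .curves import InputFunction, SessionMeta
from .exceptions import DegenerateInputError, InsufficientDataError, ValidationError
from .schedules import default_fine_grid

__all__ = [
    "BloodSampleSeries",
    "ParentFractionModel",
    "PlasmaOverBloodModel",
    "fit_parent_fraction",
    "fit_plasma_over_blood",
    "build_aif",
    "compute_suv",
    "suv_scale_factor",
    "normalize_aif_to_session",
    "build_mean_aif",
    "DEFAULT_BEGIN_MIN",
]

#: Default plateau end for the parent fraction: after the last early sample
#: (50 s) and well before the first metabolite sample (5 min).
DEFAULT_BEGIN_MIN = 0.75


@dataclass(frozen=True)
class BloodSampleSeries:
    """Discrete arterial samples for one subject/session.

    ``parent_fraction`` is NaN where not measured (it is measured only on
    the metabolite subset).  ``plasma_kBq_per_mL`` is optional; where
    present it provides the plasma-over-blood ratio points.
    """

    subject: str
    session: str
    time_min: np.ndarray
    blood_kBq_per_mL: np.ndarray
    parent_fraction: Optional[np.ndarray] = None
    plasma_kBq_per_mL: Optional[np.ndarray] = None
    sample_volume_uL: float = 200.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        b = np.asarray(self.blood_kBq_per_mL, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "blood_kBq_per_mL", b)
        if t.ndim != 1 or t.size == 0:
            raise ValidationError("sample times must be a non-empty 1-D array")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValidationError("sample times must be non-negative and strictly increasing")
        if b.shape != t.shape or np.any(b < 0) or not np.all(np.isfinite(b)):
            raise ValidationError("whole-blood activities must be finite, >= 0, one per sample")
        for name in ("parent_fraction", "plasma_kBq_per_mL"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                object.__setattr__(self, name, arr)
                if arr.shape != t.shape:
                    raise ValidationError(f"{name} must align with sample times")
        if self.parent_fraction is not None:
            pf = self.parent_fraction[np.isfinite(self.parent_fraction)]
            if np.any((pf < 0) | (pf > 1)):
                raise ValidationError("measured parent fractions must lie in [0, 1]")

    @property
    def measured_pf_mask(self) -> np.ndarray:
        if self.parent_fraction is None:
            return np.zeros_like(self.time_min, dtype=bool)
        return np.isfinite(self.parent_fraction)


@dataclass(frozen=True)
class ParentFractionModel:
    """Plateau-then-biexponential plasma parent fraction.

    pf(t) = 1 for t <= begin, and
    pf(t) = a1 exp(-b1 (t-begin)) + a2 exp(-b2 (t-begin)) for t > begin,
    with a1 + a2 = 1 (continuity at the plateau) and b1, b2 >= 0.
    """

    begin: float
    a1: float
    b1: float
    b2: float
    rss: float = 0.0

    def __post_init__(self) -> None:
        if self.begin < 0:
            raise ValidationError("begin must be >= 0 min")
        if not (0.0 <= self.a1 <= 1.0):
            raise ValidationError("a1 must lie in [0, 1] so that pf stays in [0, 1]")
        if self.b1 < 0 or self.b2 < 0:
            raise ValidationError("decay rates must be >= 0")

    @property
    def a2(self) -> float:
        return 1.0 - self.a1

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        dt = np.maximum(t - self.begin, 0.0)
        pf = self.a1 * np.exp(-self.b1 * dt) + self.a2 * np.exp(-self.b2 * dt)
        return np.where(t <= self.begin, 1.0, pf)


@dataclass(frozen=True)
class PlasmaOverBloodModel:
    """Straight-line model of the plasma/whole-blood activity ratio."""

    intercept: float
    slope: float
    nonpositive_warning: bool = False

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


def fit_parent_fraction(samples: BloodSampleSeries,
                        begin: float = DEFAULT_BEGIN_MIN) -> ParentFractionModel:
    """Constrained least-squares fit of the parent fraction to the metabolite subset."""
    mask = samples.measured_pf_mask & (samples.time_min > begin)
    t = samples.time_min[mask]
    y = samples.parent_fraction[mask] if samples.parent_fraction is not None else np.array([])
    if t.size < 2:
        raise InsufficientDataError(
            f"need >= 2 measured parent fractions after begin={begin} min, got {t.size}"
        )

    dt = t - begin

    def resid(p):
        a1, b1, b2 = p
        return a1 * np.exp(-b1 * dt) + (1 - a1) * np.exp(-b2 * dt) - y

    best = None
    # a few starts spanning fast/slow rate splits; the problem is tiny
    for b1_0, b2_0 in ((0.5, 0.02), (0.1, 0.01), (1.0, 0.1), (0.01, 0.001),
                       (0.0, 0.0)):
        sol = least_squares(resid, x0=[0.5, b1_0, b2_0],
                            bounds=([0.0, 0.0, 0.0], [1.0, 50.0, 50.0]))
        if best is None or sol.cost < best.cost:
            best = sol
    a1, b1, b2 = best.x
    # canonical ordering: b1 the faster rate
    if b2 > b1:
        a1, b1, b2 = 1.0 - a1, b2, b1
    return ParentFractionModel(begin=begin, a1=a1, b1=b1, b2=b2,
                               rss=float(2 * best.cost))


def fit_plasma_over_blood(samples: BloodSampleSeries,
                          ratios: Optional[np.ndarray] = None) -> PlasmaOverBloodModel:
    """Ordinary least-squares line through (time, plasma/blood ratio) points."""
    t = samples.time_min
    if ratios is None:
        if samples.plasma_kBq_per_mL is None:
            raise InsufficientDataError("no plasma activities or precomputed ratios available")
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(samples.blood_kBq_per_mL > 0,
                              samples.plasma_kBq_per_mL / samples.blood_kBq_per_mL, np.nan)
    ratios = np.asarray(ratios, dtype=float)
    mask = np.isfinite(ratios)
    if mask.sum() < 2:
        raise InsufficientDataError("need >= 2 plasma/blood ratio points")
    slope, intercept = np.polyfit(t[mask], ratios[mask], 1)
    line = np.polyval([slope, intercept], np.linspace(0.0, 60.0, 121))
    return PlasmaOverBloodModel(intercept=float(intercept), slope=float(slope),
                                nonpositive_warning=bool(np.any(line <= 0)))


def _interp_blood(samples: BloodSampleSeries, grid: np.ndarray) -> np.ndarray:
    """Piecewise-linear whole blood: 0 at t=0, flat beyond the last sample."""
    t = np.concatenate([[0.0], samples.time_min]) if samples.time_min[0] > 0 else samples.time_min
    v = (np.concatenate([[0.0], samples.blood_kBq_per_mL])
         if samples.time_min[0] > 0 else samples.blood_kBq_per_mL)
    return np.interp(grid, t, v)


def build_aif(samples: BloodSampleSeries,
              pf: ParentFractionModel,
              pob: PlasmaOverBloodModel,
              grid: Optional[np.ndarray] = None,
              meta: Optional[SessionMeta] = None) -> InputFunction:
    """Assemble the metabolite-corrected AIF on a fine grid.

    AIF(t) = blood(t) * pob(t) * pf(t), where blood(t) is the interpolated
    whole-blood curve, pob the plasma-over-blood ratio line and pf the
    fitted parent fraction.
    """
    if grid is None:
        grid = default_fine_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValidationError("AIF grid must be strictly increasing")
    blood = _interp_blood(samples, grid)
    ratio = pob(grid)
    if np.any(ratio <= 0):
        raise ValidationError("plasma-over-blood line is nonpositive inside the grid")
    plasma_total = blood * ratio
    aif = plasma_total * pf(grid)
    return InputFunction(t_min=grid, plasma=aif, blood=blood,
                         provenance="measured", meta=meta)


def compute_suv(concentration_Bq_per_mL, dose_Bq: float, weight_g: float,
                convention: str = "as-printed"):
    """Standardized uptake value of an activity concentration.

    Two conventions are provided.  ``as-printed`` (the default) divides the
    concentration by dose x weight; ``conventional`` is the textbook SUV,
    concentration x weight / dose.  The choice also governs the scalar used
    for cross-session AIF normalization (see :func:`suv_scale_factor`).
    """
    if not dose_Bq > 0:
        raise ValidationError("dose must be > 0")
    if not weight_g > 0:
        raise ValidationError("weight must be > 0")
    c = np.asarray(concentration_Bq_per_mL, dtype=float)
    if convention == "as-printed":
        out = c / (dose_Bq * weight_g)
    elif convention == "conventional":
        out = c * weight_g / dose_Bq
    else:
        raise ValidationError(f"unknown SUV convention {convention!r}")
    return float(out) if np.isscalar(concentration_Bq_per_mL) else out


def suv_scale_factor(source: SessionMeta, target: SessionMeta,
                     convention: str = "as-printed") -> float:
    """Scalar mapping a source-session AIF to a target session.

    Derived from assuming the AIF is invariant in SUV units across sessions:
    the target AIF is the source AIF times the ratio of the sessions'
    SUV denominators.
    """
    if convention == "as-printed":
        return (target.dose_MBq * target.weight_g) / (source.dose_MBq * source.weight_g)
    if convention == "conventional":
        return (target.dose_MBq / target.weight_g) / (source.dose_MBq / source.weight_g)
    raise ValidationError(f"unknown SUV convention {convention!r}")


def normalize_aif_to_session(source: InputFunction,
                             source_meta: SessionMeta,
                             target_meta: SessionMeta,
                             convention: str = "as-printed") -> InputFunction:
    """Derive a session's AIF by dose/weight rescaling of a measured (or mean) AIF."""
    if source.provenance not in ("measured", "mean-derived"):
        raise ValidationError("can only normalize a measured or mean-derived AIF")
    if source.provenance == "measured" and source_meta.subject != target_meta.subject:
        raise ValidationError("measured AIFs may only be normalized within a subject")
    s = suv_scale_factor(source_meta, target_meta, convention)
    return source.scaled(s, provenance="session-derived", meta=target_meta)


def build_mean_aif(aifs: Sequence[InputFunction],
                   metas: Sequence[SessionMeta],
                   grid: Optional[np.ndarray] = None) -> InputFunction:
    """Cohort mean AIF from the sessions with arterial sampling.

    Each AIF is resampled to a common grid and min-max rescaled to [0, 1];
    the rescaled curves are averaged pointwise, and the average is restored
    to concentration units with the mean of the individual (max - min)
    amplitudes.  The mean injected dose and mean weight are attached so the
    mean AIF can be renormalized to any session.
    """
    if len(aifs) < 2:
        raise InsufficientDataError("need >= 2 AIFs to build a mean AIF")
    if len(metas) != len(aifs):
        raise ValidationError("one SessionMeta per AIF required")
    for a in aifs:
        if a.provenance != "measured":
            raise ValidationError("mean AIF must be built from measured AIFs only")
    if grid is None:
        grid = default_fine_grid()
    grid = np.asarray(grid, dtype=float)

    normed, amps, bloods = [], [], []
    for a in aifs:
        p = a.plasma_at(grid)
        lo, hi = float(p.min()), float(p.max())
        if hi <= lo:
            raise DegenerateInputError("flat AIF (max == min) cannot be min-max rescaled")
        normed.append((p - lo) / (hi - lo))
        amps.append(hi - lo)
        if a.blood is not None:
            bloods.append(a.blood_at(grid))
    mean_amp = float(np.mean(amps))
    plasma = np.mean(normed, axis=0) * mean_amp
    plasma[grid == 0.0] = 0.0
    blood = np.mean(bloods, axis=0) if len(bloods) == len(aifs) else None
    mean_meta = SessionMeta(
        subject="__mean__",
        session=metas[0].session,
        dose_MBq=float(np.mean([m.dose_MBq for m in metas])),
        weight_g=float(np.mean([m.weight_g for m in metas])),
    )
    return InputFunction(t_min=grid, plasma=plasma, blood=blood,
                         provenance="mean-derived", meta=mean_meta)
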