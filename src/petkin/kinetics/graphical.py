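"""Logan graphical analysis with plasma input or a reference region.

Both variants linearize the compartment equations at late times:

* plasma input:  int_0^t C_T / C_T(t)  vs  int_0^t C_p / C_T(t);
  the late-time slope is V_T;
* reference tissue:  int_0^t C_T / C_T(t)  vs
  (int_0^t C_ref + C_ref/k2') / C_T(t); the slope is the DVR
  (= BP_ND + 1).  When no k2' is supplied the C_ref/k2' term is dropped
  (late-time approximation) and a warning is recorded.

Plasma integrals use trapezoid quadrature on the AIF's fine grid; tissue
integrals use trapezoid quadrature on frame mid-times with the curve
anchored at (0, 0).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..curves import InputFunction, TimeActivityCurve
from ..exceptions import ValidationError
from .base import KineticModelBase, KineticResults

__all__ = ["LoganPlot", "LoganReference", "logan_vt", "logan_ref_dvr"]

DEFAULT_T_STAR_MIN = 15.0


def _tissue_integral(mid_min: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid of a frame-value curve at its mid-times, from (0,0)."""
    t = np.concatenate([[0.0], mid_min])
    v = np.concatenate([[0.0], values])
    seg = np.diff(t) * (v[:-1] + v[1:]) / 2.0
    return np.cumsum(seg)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


class LoganPlot(KineticModelBase):
    """Logan plot with arterial plasma input; the late-time slope is V_T."""

    model_name = "LP"

    def __init__(self, tac: TimeActivityCurve, aif: InputFunction,
                 t_star: float = DEFAULT_T_STAR_MIN):
        super().__init__(tac, weights="uniform")
        self.aif = aif
        self.t_star = float(t_star)

    def fit(self) -> KineticResults:
        mid = self.tac.mid_min
        ct = self.tac.values
        late = mid >= self.t_star
        warnings = []
        usable = late & (ct > 0)
        if np.any(late & ~usable):
            warnings.append("nonpositive tissue values in the Logan window were dropped")
        if usable.sum() < 3:
            res = self._failure("fewer than 3 usable frames after t_star")
            res.warnings = warnings
            return res

        int_ct = _tissue_integral(mid, ct)
        cum_cp = np.concatenate(
            [[0.0], np.cumsum(np.diff(self.aif.t_min)
                              * (self.aif.plasma[:-1] + self.aif.plasma[1:]) / 2.0)])
        int_cp = np.interp(mid, self.aif.t_min, cum_cp)

        x = int_cp[usable] / ct[usable]
        y = int_ct[usable] / ct[usable]
        slope, intercept = _ols_line(x, y)
        return KineticResults(model=self.model_name, params={},
                              vt=slope, intercept=intercept,
                              wrss=float(np.sum((y - slope * x - intercept) ** 2)),
                              tac=self.tac, warnings=warnings)


class LoganReference(KineticModelBase):
    """Logan reference-tissue plot; the late-time slope is the DVR."""

    model_name = "LR"

    def __init__(self, tac: TimeActivityCurve, ref_tac: TimeActivityCurve,
                 k2_prime: Optional[float] = None,
                 t_star: float = DEFAULT_T_STAR_MIN):
        super().__init__(tac, weights="uniform")
        if ref_tac.schedule.n_frames != tac.schedule.n_frames:
            raise ValidationError("target and reference must share the frame schedule")
        if k2_prime is not None and not k2_prime > 0:
            raise ValidationError("k2_prime must be > 0 when given")
        self.ref_tac = ref_tac
        self.k2_prime = k2_prime
        self.t_star = float(t_star)

    def fit(self) -> KineticResults:
        mid = self.tac.mid_min
        ct = self.tac.values
        cref = self.ref_tac.values
        late = mid >= self.t_star
        warnings = []
        usable = late & (ct > 0)
        if np.any(late & ~usable):
            warnings.append("nonpositive tissue values in the Logan window were dropped")
        if usable.sum() < 3:
            res = self._failure("fewer than 3 usable frames after t_star")
            res.warnings = warnings
            return res

        int_ct = _tissue_integral(mid, ct)
        int_cref = _tissue_integral(mid, cref)
        numer = int_cref.copy()
        if self.k2_prime is not None:
            numer = numer + cref / self.k2_prime
        else:
            warnings.append("k2_prime absent: late-time approximation without C_ref/k2' term")

        x = numer[usable] / ct[usable]
        y = int_ct[usable] / ct[usable]
        slope, intercept = _ols_line(x, y)
        return KineticResults(model=self.model_name, params={},
                              bp_nd=slope - 1.0, dvr=slope, intercept=intercept,
                              wrss=float(np.sum((y - slope * x - intercept) ** 2)),
                              tac=self.tac, warnings=warnings)


def logan_vt(tac: TimeActivityCurve, aif: InputFunction,
             t_star: float = DEFAULT_T_STAR_MIN) -> KineticResults:
    """Convenience wrapper: LoganPlot(tac, aif, t_star).fit()."""
    return LoganPlot(tac, aif, t_star=t_star).fit()


def logan_ref_dvr(tac: TimeActivityCurve, ref_tac: TimeActivityCurve,
                  k2_prime: Optional[float] = None,
                  t_star: float = DEFAULT_T_STAR_MIN) -> KineticResults:
    """Convenience wrapper: LoganReference(tac, ref_tac, k2_prime, t_star).fit()."""
    return LoganReference(tac, ref_tac, k2_prime=k2_prime, t_star=t_star).fit()
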