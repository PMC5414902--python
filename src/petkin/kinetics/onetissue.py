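"""One-tissue compartment model (1TC).

The tissue concentration follows dC_T/dt = K1 C_p(t) - k2 C_T(t), i.e.
C_T = K1 (C_p * exp(-k2 t)); the total volume of distribution is
V_T = K1/k2.  Model frame values are the average of the instantaneous
solution over each frame interval (mid-time sampling would be inaccurate
for the 900 s late frames).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from ..curves import InputFunction, TimeActivityCurve
from ..exceptions import ValidationError
from ..schedules import FrameSchedule
from .base import KineticModelBase, KineticResults
from .conv import expconv, frame_average_matrix

__all__ = ["solve_1tc_tac", "OneTissueModel", "fit_1tc"]

K1_BOUNDS = (0.0, 10.0)
K2_BOUNDS = (1e-4, 10.0)


def _check_coverage(aif: InputFunction, schedule: FrameSchedule) -> None:
    if schedule.end_s[-1] / 60.0 > aif.t_min[-1] + 1e-9:
        raise ValidationError("frame schedule extends past the AIF time grid")


def solve_1tc_tac(K1: float, k2: float, aif: InputFunction,
                  schedule: FrameSchedule,
                  subject: str = "", session: str = "",
                  region: str = "", side: str = "unpaired") -> TimeActivityCurve:
    """Forward-simulate a 1TC TAC on the AIF's fine grid, frame-averaged."""
    if K1 < 0:
        raise ValidationError("K1 must be >= 0")
    if not k2 > 0:
        raise ValidationError("k2 must be > 0")
    _check_coverage(aif, schedule)
    inst = K1 * expconv(aif.plasma, k2, aif.t_min)
    A = frame_average_matrix(aif.t_min, schedule.start_s, schedule.end_s)
    return TimeActivityCurve(subject=subject, session=session, region=region,
                             side=side, schedule=schedule, values=A @ inst)


class OneTissueModel(KineticModelBase):
    """Weighted nonlinear least-squares 1TC fit of a regional TAC.

    Parameters are bounded (K1 in [0, 10] mL/cm^3/min, k2 in [1e-4, 10]
    /min) and the optimizer is restarted from several log-spaced k2 values
    to avoid local minima.
    """

    model_name = "1TC"

    def __init__(self, tac: TimeActivityCurve, aif: InputFunction,
                 weights: str = "frame_duration"):
        super().__init__(tac, weights)
        if tac.schedule.n_frames < 4:
            raise ValidationError("1TC fit needs >= 4 frames")
        _check_coverage(aif, tac.schedule)
        self.aif = aif
        self._A = frame_average_matrix(aif.t_min, tac.schedule.start_s,
                                       tac.schedule.end_s)
        self._sqw = np.sqrt(self.weights)

    def predict(self, K1: float, k2: float) -> np.ndarray:
        return self._A @ (K1 * expconv(self.aif.plasma, k2, self.aif.t_min))

    def fit(self, n_starts: int = 5,
            k2_start_range: tuple = (1e-3, 1.0)) -> KineticResults:
        y = self.tac.values
        if not np.any(y != 0):
            return self._failure("degenerate")

        def resid(p):
            return (self.predict(p[0], p[1]) - y) * self._sqw

        k1_0 = max(float(np.max(y)) / max(float(np.max(self.aif.plasma)), 1e-12), 1e-3)
        best, n_iter = None, 0
        for k2_0 in np.geomspace(*k2_start_range, n_starts):
            sol = least_squares(resid, x0=[min(k1_0, K1_BOUNDS[1]), k2_0],
                                bounds=([K1_BOUNDS[0], K2_BOUNDS[0]],
                                        [K1_BOUNDS[1], K2_BOUNDS[1]]))
            n_iter += sol.nfev
            if sol.status > 0 and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            return self._failure("optimizer did not converge from any start")
        K1, k2 = best.x
        se = _se_from_jacobian(best, y.size)
        res = KineticResults(
            model=self.model_name,
            params={"K1": K1, "k2": k2},
            param_se={"K1": se[0], "k2": se[1]},
            vt=K1 / k2,
            vt_se=_vt_se_1tc(best, K1, k2, y.size),
            wrss=float(2 * best.cost),
            n_iter=n_iter,
            converged=True,
            tac=self.tac,
            fitted_values=self.predict(K1, k2),
        )
        return res


def _se_from_jacobian(sol, n_obs: int) -> np.ndarray:
    """Asymptotic standard errors from the least-squares Jacobian."""
    J = sol.jac
    dof = max(n_obs - J.shape[1], 1)
    s2 = 2 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(J.shape[1], np.nan)


def _vt_se_1tc(sol, K1: float, k2: float, n_obs: int) -> float:
    """Delta-method SE of V_T = K1/k2."""
    J = sol.jac
    dof = max(n_obs - J.shape[1], 1)
    s2 = 2 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return float("nan")
    g = np.array([1.0 / k2, -K1 / k2 ** 2])
    return float(np.sqrt(max(g @ cov @ g, 0.0)))


def fit_1tc(tac: TimeActivityCurve, aif: InputFunction,
            weights: str = "frame_duration") -> KineticResults:
    """Convenience wrapper: OneTissueModel(tac, aif).fit()."""
    return OneTissueModel(tac, aif, weights=weights).fit()
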