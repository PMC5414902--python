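"""Two-tissue compartment model (2TC).

C_T = C_1 + C_2 with
    dC_1/dt = K1 C_p - (k2 + k3) C_1 + k4 C_2
    dC_2/dt = k3 C_1 - k4 C_2
whose impulse response is a sum of two exponentials with rates
alpha_{1,2} = ((s +/- sqrt(s^2 - 4 k2 k4)) / 2), s = k2 + k3 + k4, and
V_T = (K1/k2)(1 + k3/k4).

This model is numerically fragile on noisy small-animal data (many fits
hit bounds or return huge V_T uncertainties), so the fit flags — rather
than raises on — non-convergence, boundary-pinned parameters and a
relative V_T standard error above 100%.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from ..curves import InputFunction, TimeActivityCurve
from ..exceptions import ValidationError
from ..schedules import FrameSchedule
from .base import KineticModelBase, KineticResults
from .conv import expconv, frame_average_matrix
from .onetissue import _check_coverage

__all__ = ["solve_2tc_tac", "TwoTissueModel", "fit_2tc"]

LOWER = np.array([0.0, 1e-4, 0.0, 1e-4])
UPPER = np.array([10.0, 10.0, 10.0, 10.0])


def _alphas(k2: float, k3: float, k4: float) -> tuple[float, float]:
    s = k2 + k3 + k4
    disc = max(s * s - 4.0 * k2 * k4, 0.0)
    root = np.sqrt(disc)
    return (s - root) / 2.0, (s + root) / 2.0


def _impulse_coeffs(K1, k2, k3, k4):
    a1, a2 = _alphas(k2, k3, k4)
    denom = a2 - a1
    if denom < 1e-12:  # repeated root; nudge apart (measure-zero configuration)
        a2 = a1 + 1e-12
        denom = 1e-12
    c1 = K1 * (k3 + k4 - a1) / denom
    c2 = K1 * (a2 - k3 - k4) / denom
    return (c1, a1), (c2, a2)


def solve_2tc_tac(K1, k2, k3, k4, aif: InputFunction, schedule: FrameSchedule,
                  **tac_kwargs) -> TimeActivityCurve:
    """Forward-simulate a 2TC TAC (frame-averaged) by double exponential convolution."""
    if min(K1, k3) < 0 or min(k2, k4) <= 0:
        raise ValidationError("2TC rates must be K1,k3 >= 0 and k2,k4 > 0")
    _check_coverage(aif, schedule)
    inst = _instantaneous(K1, k2, k3, k4, aif)
    A = frame_average_matrix(aif.t_min, schedule.start_s, schedule.end_s)
    defaults = dict(subject="", session="", region="", side="unpaired")
    defaults.update(tac_kwargs)
    return TimeActivityCurve(schedule=schedule, values=A @ inst, **defaults)


def _instantaneous(K1, k2, k3, k4, aif: InputFunction) -> np.ndarray:
    (c1, a1), (c2, a2) = _impulse_coeffs(K1, k2, k3, k4)
    return (c1 * expconv(aif.plasma, a1, aif.t_min)
            + c2 * expconv(aif.plasma, a2, aif.t_min))


class TwoTissueModel(KineticModelBase):
    """Weighted nonlinear least-squares 2TC fit with failure flagging."""

    model_name = "2TC"

    def __init__(self, tac: TimeActivityCurve, aif: InputFunction,
                 weights: str = "frame_duration"):
        super().__init__(tac, weights)
        if tac.schedule.n_frames < 4:
            raise ValidationError("2TC fit needs >= 4 frames")
        _check_coverage(aif, tac.schedule)
        self.aif = aif
        self._A = frame_average_matrix(aif.t_min, tac.schedule.start_s,
                                       tac.schedule.end_s)
        self._sqw = np.sqrt(self.weights)

    def predict(self, K1, k2, k3, k4) -> np.ndarray:
        return self._A @ _instantaneous(K1, k2, k3, k4, self.aif)

    def fit(self, n_starts: int = 4) -> KineticResults:
        y = self.tac.values
        if not np.any(y != 0):
            return self._failure("degenerate")

        def resid(p):
            return (self.predict(*p) - y) * self._sqw

        k1_0 = max(float(np.max(y)) / max(float(np.max(self.aif.plasma)), 1e-12), 1e-3)
        starts = [
            [k1_0, 0.1, 0.05, 0.05],
            [k1_0, 0.5, 0.01, 0.01],
            [k1_0, 0.05, 0.1, 0.02],
            [k1_0, 0.2, 0.02, 0.1],
        ][:n_starts]
        best, n_iter = None, 0
        for x0 in starts:
            x0 = np.clip(x0, LOWER + 1e-6, UPPER - 1e-6)
            sol = least_squares(resid, x0=x0, bounds=(LOWER, UPPER))
            n_iter += sol.nfev
            if sol.status > 0 and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            return self._failure("optimizer did not converge from any start")

        K1, k2, k3, k4 = best.x
        vt = (K1 / k2) * (1.0 + k3 / k4)
        res = KineticResults(
            model=self.model_name,
            params={"K1": K1, "k2": k2, "k3": k3, "k4": k4},
            vt=vt,
            wrss=float(2 * best.cost),
            n_iter=n_iter,
            converged=True,
            tac=self.tac,
            fitted_values=self.predict(K1, k2, k3, k4),
        )
        # failure screens mirroring the instability of this model class
        pinned = np.any(np.isclose(best.x[[1, 3]], LOWER[[1, 3]], atol=1e-8)) or \
            np.any(np.isclose(best.x, UPPER, rtol=1e-6))
        vt_se = _vt_se_2tc(best, K1, k2, k3, k4, y.size)
        res.vt_se = vt_se
        if pinned:
            res.failed = True
            res.failure_reason = "parameter pinned at bound"
        elif np.isfinite(vt_se) and vt > 0 and vt_se / vt > 1.0:
            res.failed = True
            res.failure_reason = "relative SE of V_T exceeds 100%"
        return res


def _vt_se_2tc(sol, K1, k2, k3, k4, n_obs: int) -> float:
    J = sol.jac
    dof = max(n_obs - J.shape[1], 1)
    s2 = 2 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return float("inf")
    g = np.array([
        (1.0 + k3 / k4) / k2,
        -K1 * (1.0 + k3 / k4) / k2 ** 2,
        K1 / (k2 * k4),
        -K1 * k3 / (k2 * k4 ** 2),
    ])
    return float(np.sqrt(max(g @ cov @ g, 0.0)))


def fit_2tc(tac: TimeActivityCurve, aif: InputFunction,
            weights: str = "frame_duration") -> KineticResults:
    """Convenience wrapper: TwoTissueModel(tac, aif).fit()."""
    return TwoTissueModel(tac, aif, weights=weights).fit()
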