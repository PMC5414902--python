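"""Shared machinery for kinetic models: weights, results container, summary."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from ..curves import TimeActivityCurve
from ..exceptions import ValidationError

__all__ = ["KineticResults", "KineticModelBase", "frame_weights", "bp_to_dvr"]


def bp_to_dvr(bp: float) -> float:
    """Distribution volume ratio from binding potential: DVR = BP_ND + 1.

    DVR is preferred for summaries because BP_ND may legitimately be
    negative when the target binds less than the reference region.
    """
    return bp + 1.0


def frame_weights(schedule, scheme: str = "frame_duration") -> np.ndarray:
    """Per-frame fit weights, normalized to mean 1.

    ``frame_duration`` weights frames by their length — the standard proxy
    for count statistics with decay-corrected data; ``uniform`` weights all
    frames equally.
    """
    if scheme == "frame_duration":
        w = schedule.duration_s.astype(float)
    elif scheme == "uniform":
        w = np.ones(schedule.n_frames)
    else:
        raise ValidationError(f"unknown weighting scheme {scheme!r}")
    return w / w.mean()


@dataclass
class KineticResults:
    """Fit results for one TAC under one kinetic model.

    ``params`` holds the micro-parameters (K1, k2, ... or R1, k2, k2a);
    macro-parameters live in ``vt`` (plasma-input models) or
    ``bp_nd``/``dvr`` (reference-tissue models).  ``failed`` is a flag,
    never an exception, so cohort runs always complete.
    """

    model: str
    params: Dict[str, float] = field(default_factory=dict)
    param_se: Dict[str, float] = field(default_factory=dict)
    vt: Optional[float] = None
    vt_se: Optional[float] = None
    bp_nd: Optional[float] = None
    dvr: Optional[float] = None
    intercept: Optional[float] = None
    wrss: Optional[float] = None
    n_iter: int = 0
    converged: bool = True
    failed: bool = False
    failure_reason: str = ""
    warnings: list = field(default_factory=list)
    tac: Optional[TimeActivityCurve] = None
    fitted_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.bp_nd is not None and self.dvr is None:
            self.dvr = bp_to_dvr(self.bp_nd)

    @property
    def residuals(self) -> Optional[np.ndarray]:
        if self.tac is None or self.fitted_values is None:
            return None
        return self.tac.values - self.fitted_values

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels spirit."""
        lines = [f"Kinetic model: {self.model}"]
        if self.tac is not None:
            lines.append(
                f"TAC: {self.tac.subject}/{self.tac.session} "
                f"{self.tac.region} ({self.tac.side})"
            )
        lines.append("-" * 46)
        for name, value in self.params.items():
            se = self.param_se.get(name)
            se_txt = f" +/- {se:.4g}" if se is not None else ""
            lines.append(f"{name:>10s} = {value:.6g}{se_txt}")
        if self.vt is not None:
            se_txt = f" +/- {self.vt_se:.4g}" if self.vt_se is not None else ""
            lines.append(f"{'V_T':>10s} = {self.vt:.6g}{se_txt}  (mL/cm^3)")
        if self.bp_nd is not None:
            lines.append(f"{'BP_ND':>10s} = {self.bp_nd:.6g}")
            lines.append(f"{'DVR':>10s} = {self.dvr:.6g}")
        if self.intercept is not None:
            lines.append(f"{'intercept':>10s} = {self.intercept:.6g}")
        if self.wrss is not None:
            lines.append(f"{'WRSS':>10s} = {self.wrss:.6g}")
        lines.append(f"converged: {self.converged}   iterations: {self.n_iter}")
        if self.failed:
            lines.append(f"FAILED: {self.failure_reason}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Data points and fitted curve against frame mid-times."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.tac is not None:
            ax.plot(self.tac.mid_min, self.tac.values, "o", label="data")
            if self.fitted_values is not None:
                ax.plot(self.tac.mid_min, self.fitted_values, "-",
                        label=f"{self.model} fit")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("activity (kBq/mL)")
        ax.legend()
        return ax

    def to_row(self) -> dict:
        """Flat record for results tables."""
        row = {
            "model": self.model,
            "V_T": self.vt, "BP_ND": self.bp_nd, "DVR": self.dvr,
            "wrss": self.wrss, "converged": self.converged,
            "failed": self.failed, "failure_reason": self.failure_reason,
        }
        if self.tac is not None:
            row.update(subject=self.tac.subject, session=self.tac.session,
                       region=self.tac.region, side=self.tac.side)
        for name, value in self.params.items():
            row[name] = value
        return row


class KineticModelBase:
    """Common constructor for models fitted to a single TAC."""

    model_name = "base"

    def __init__(self, tac: TimeActivityCurve, weights: str = "frame_duration"):
        self.tac = tac
        self.schedule = tac.schedule
        self.weights = frame_weights(tac.schedule, weights)

    def _failure(self, reason: str) -> KineticResults:
        return KineticResults(model=self.model_name, failed=True,
                              failure_reason=reason, converged=False, tac=self.tac)
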