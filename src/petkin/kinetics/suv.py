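"""Standardized uptake value summaries of regional TACs."""

from __future__ import annotations

from typing import Tuple

import numpy as np

from ..curves import SessionMeta, TimeActivityCurve
from ..exceptions import ValidationError
from ..input_function import compute_suv

__all__ = ["suv_summary", "window_mean"]

DEFAULT_SUV_WINDOW = (0.0, 60.0)


def window_mean(tac: TimeActivityCurve, window: Tuple[float, float]) -> float:
    """Frame-duration-weighted mean concentration over frames whose
    mid-time lies inside ``window`` (minutes)."""
    lo, hi = window
    if not hi > lo:
        raise ValidationError("SUV window must have positive length")
    mid = tac.mid_min
    mask = (mid >= lo) & (mid <= hi)
    if not np.any(mask):
        raise ValidationError("SUV window contains no frames")
    dur = tac.schedule.duration_s[mask]
    return float(np.sum(tac.values[mask] * dur) / np.sum(dur))


def suv_summary(tac: TimeActivityCurve, meta: SessionMeta,
                window: Tuple[float, float] = DEFAULT_SUV_WINDOW,
                convention: str = "as-printed") -> float:
    """SUV of the window-averaged regional concentration.

    The TAC is in kBq/mL; the concentration is converted to Bq/mL before
    the dose (Bq) and weight (g) normalization.
    """
    mean_kBq = window_mean(tac, window)
    return compute_suv(mean_kBq * 1000.0, meta.dose_Bq, meta.weight_g,
                       convention=convention)
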