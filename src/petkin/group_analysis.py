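"""Group-level longitudinal statistics over regional results.

Conventions: a change in a bilateral structure counts as significant only
when it is significant on both the left and the right side; percent
changes are expressed relative to the earlier session; intersubject
variability is summarized by the coefficient of variation with a 20%
qualitative gate; per-region p-values are reported uncorrected (an
optional Bonferroni switch exists but is off by default), with a paired t
test as primary and a Mann-Whitney U test as robustness check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, InsufficientDataError, ValidationError

__all__ = [
    "percent_change",
    "bilateral_significance",
    "paired_t_test",
    "mann_whitney_u",
    "coefficient_of_variation",
    "correlation",
    "aggregate_regions",
    "compare_sessions",
    "DEFAULT_VENTRICLE_LABELS",
]

DEFAULT_VENTRICLE_LABELS = ("lateral ventricles", "third ventricle", "fourth ventricle")
COV_GATE_PERCENT = 20.0
EXACT_MWU_MAX_N = 8


def percent_change(earlier: float, later: float) -> float:
    """100 x (later - earlier) / earlier; decreases come out negative."""
    if earlier == 0:
        raise DegenerateInputError("percent change undefined for an earlier value of 0")
    return 100.0 * (later - earlier) / earlier


def bilateral_significance(p_left: float, p_right: float, alpha: float) -> bool:
    """True iff both sides are significant (strict inequality at the boundary)."""
    for p in (p_left, p_right):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"p-value {p} outside [0, 1]")
    return p_left < alpha and p_right < alpha


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def paired_t_test(before: Sequence[float], after: Sequence[float]) -> TestResult:
    """Two-sided paired t test on within-subject differences.

    Zero-variance differences make the t statistic undefined; that case is
    reported as degenerate with p = 1 rather than raising.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValidationError("paired samples must have equal length")
    if before.size < 2:
        raise InsufficientDataError("paired t test needs n >= 2")
    d = after - before
    if np.allclose(d, d[0]) and (np.std(d, ddof=1) == 0):
        if d[0] == 0:
            return TestResult(statistic=0.0, p_value=1.0, degenerate=True)
        return TestResult(statistic=np.inf * np.sign(d[0]), p_value=0.0, degenerate=True)
    t, p = stats.ttest_rel(after, before)
    return TestResult(statistic=float(t), p_value=float(p))


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution (full enumeration) when the smaller group has
    <= 8 observations and the data are tie-free; normal approximation with
    tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= EXACT_MWU_MAX_N and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue))


def coefficient_of_variation(values: Sequence[float]) -> float:
    """100 x sample standard deviation (n-1) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("CoV needs n >= 2")
    m = v.mean()
    if m == 0:
        raise DegenerateInputError("CoV undefined for zero mean")
    return 100.0 * v.std(ddof=1) / m


def correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("correlation needs equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("correlation undefined for zero variance")
    return float(stats.pearsonr(x, y).statistic)


def aggregate_regions(table: pd.DataFrame,
                      pairing: str = "mean-of-sides",
                      exclusions: Sequence[str] = DEFAULT_VENTRICLE_LABELS,
                      value_col: str = "value") -> pd.DataFrame:
    """Aggregate a long region-result table into per-region group summaries.

    ``table`` has columns subject, session, region, side, model, metric,
    ``value_col``; missing values mark failed fits and are excluded from
    means but counted.  ``mean-of-sides`` averages left/right within
    subject before the group mean; ``per-side`` keeps sides separate
    (needed for the bilateral significance rule).  Regions listed in
    ``exclusions`` (default: the ventricles) are removed first.
    """
    if table.empty:
        raise ValidationError("cannot aggregate an empty result table")
    if pairing not in ("mean-of-sides", "per-side"):
        raise ValidationError(f"unknown pairing mode {pairing!r}")
    df = table[~table["region"].isin(set(exclusions))].copy()

    keys = ["model", "metric", "session", "region"]
    if pairing == "mean-of-sides":
        per_subject = (df.groupby(keys + ["subject"], sort=True)[value_col]
                       .mean().reset_index())
    else:
        keys = keys + ["side"]
        per_subject = df.rename(columns={value_col: value_col})[
            keys + ["subject", value_col]]

    grouped = per_subject.groupby(keys, sort=True)[value_col]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1),
                      n=lambda v: int(v.notna().sum())).reset_index()
    failures = (df.groupby(keys, sort=True)[value_col]
                .agg(lambda v: int(v.isna().sum())).reset_index()
                .rename(columns={value_col: "failures"}))
    out = out.merge(failures, on=keys, how="left")
    out["failures"] = out["failures"].fillna(0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["cov_percent"] = 100.0 * out["sd"] / out["mean"]
    out["high_cov_flag"] = out["cov_percent"] >= COV_GATE_PERCENT
    return out


def compare_sessions(table: pd.DataFrame,
                     earlier: str, later: str,
                     alpha: float = 0.05,
                     exclusions: Sequence[str] = DEFAULT_VENTRICLE_LABELS,
                     bonferroni: bool = False,
                     value_col: str = "value") -> pd.DataFrame:
    """Region-wise longitudinal comparison between two sessions.

    For every (model, metric, region): per-side paired t and Mann-Whitney
    U tests across subjects, the bilateral-significance flag for each
    test, and the percent change of the group mean (mean-of-sides)
    relative to the earlier session.  Subjects missing either session's
    value for a side are dropped listwise for that side.
    """
    df = table[~table["region"].isin(set(exclusions))]
    df = df[df["session"].isin([earlier, later])]
    rows = []
    for (model, metric, region), sub in df.groupby(["model", "metric", "region"],
                                                   sort=True):
        p_t, p_u = {}, {}
        for side in ("left", "right"):
            wide = (sub[sub["side"] == side]
                    .pivot_table(index="subject", columns="session",
                                 values=value_col, aggfunc="first")
                    .dropna())
            if wide.shape[0] >= 2 and {earlier, later} <= set(wide.columns):
                before, after = wide[earlier].to_numpy(), wide[later].to_numpy()
                p_t[side] = paired_t_test(before, after).p_value
                p_u[side] = mann_whitney_u(before, after).p_value
            else:
                p_t[side] = np.nan
                p_u[side] = np.nan
        n_tests = df.groupby(["model", "metric", "region"]).ngroups if bonferroni else 1
        alpha_eff = alpha / n_tests

        per_subject = (sub.groupby(["subject", "session"])[value_col]
                       .mean().unstack("session"))
        mean_earlier = per_subject[earlier].mean() if earlier in per_subject else np.nan
        mean_later = per_subject[later].mean() if later in per_subject else np.nan
        pct = (percent_change(mean_earlier, mean_later)
               if np.isfinite(mean_earlier) and mean_earlier != 0
               and np.isfinite(mean_later) else np.nan)

        def _flag(p):
            return (bool(bilateral_significance(p["left"], p["right"], alpha_eff))
                    if np.isfinite(p["left"]) and np.isfinite(p["right"]) else False)

        rows.append({
            "model": model, "metric": metric, "region": region,
            "earlier": earlier, "later": later,
            "mean_earlier": mean_earlier, "mean_later": mean_later,
            "percent_change": pct,
            "p_t_left": p_t["left"], "p_t_right": p_t["right"],
            "p_u_left": p_u["left"], "p_u_right": p_u["right"],
            "bilateral_t": _flag(p_t), "bilateral_u": _flag(p_u),
            "alpha": alpha_eff,
        })
    return pd.DataFrame(rows)
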