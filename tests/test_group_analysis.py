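"""Group statistics: percent change, bilateral rule, paired t, Mann-Whitney U
(against a brute-force enumeration oracle), CoV, correlation, aggregation."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from petkin.exceptions import (DegenerateInputError, InsufficientDataError,
                               ValidationError)
from petkin.group_analysis import (aggregate_regions, bilateral_significance,
                                   coefficient_of_variation, compare_sessions,
                                   correlation, mann_whitney_u, paired_t_test,
                                   percent_change)


class TestPercentChange:
    def test_increase_relative_to_earlier(self):
        assert percent_change(1.00, 2.18) == pytest.approx(118.0)

    def test_no_change(self):
        assert percent_change(3.7, 3.7) == 0.0

    def test_decrease_is_negative(self):
        assert percent_change(2.18, 1.025) == pytest.approx(-53.0, abs=0.1)

    def test_zero_earlier_raises(self):
        with pytest.raises(DegenerateInputError):
            percent_change(0.0, 1.0)

    @given(a=st.floats(0.05, 50.0), b=st.floats(0.05, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_reciprocity_identity(self, a, b):
        p_ab = percent_change(a, b)
        p_ba = percent_change(b, a)
        assert (1 + p_ab / 100.0) * (1 + p_ba / 100.0) == pytest.approx(1.0)


class TestBilateralRule:
    @pytest.mark.parametrize("pl,pr,alpha,expected", [
        (0.01, 0.04, 0.05, True),
        (0.01, 0.06, 0.05, False),
        (0.05, 0.05, 0.05, False),  # strict at the boundary
    ])
    def test_examples(self, pl, pr, alpha, expected):
        assert bilateral_significance(pl, pr, alpha) is expected

    @given(pl=st.floats(0.0, 1.0), pr=st.floats(0.0, 1.0),
           alpha=st.floats(0.001, 0.5), bump=st.floats(0.0, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_alpha(self, pl, pr, alpha, bump):
        if bilateral_significance(pl, pr, alpha):
            assert bilateral_significance(pl, pr, min(alpha + bump, 1.0))

    def test_invalid_p_value_rejected(self):
        with pytest.raises(ValidationError):
            bilateral_significance(-0.1, 0.5, 0.05)


class TestPairedT:
    def test_constant_shift_with_jitter_is_significant(self):
        rng = np.random.default_rng(5)
        before = np.array([1.0, 1.2, 0.9, 1.1, 1.05])
        after = before + 1.0 + rng.normal(0.0, 1e-4, size=5)
        res = paired_t_test(before, after)
        assert res.p_value < 1e-6

    def test_identical_samples_degenerate(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0

    def test_symmetric_differences_give_t_zero(self):
        before = np.zeros(4)
        after = np.array([1.0, -1.0, 1.0, -1.0])
        res = paired_t_test(before, after)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])


def _mwu_exact_oracle(a, b):
    """Brute-force two-sided exact Mann-Whitney p by full enumeration."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n_a, n = a.size, pooled.size
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    center = n_a * (n - n_a) / 2.0
    count = total = 0
    for idx in combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_groups(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert min(res.statistic, 9 - res.statistic) == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert _mwu_exact_oracle([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("n_a,n_b", [(n_a, n_b) for n_a in range(2, 6)
                                         for n_b in range(2, 6)])
    def test_exact_matches_enumeration_oracle(self, n_a, n_b):
        rng = np.random.default_rng(100 * n_a + n_b)
        a = rng.normal(0.0, 1.0, n_a)
        b = rng.normal(0.7, 1.0, n_b)
        res = mann_whitney_u(a, b)
        assert res.p_value == pytest.approx(_mwu_exact_oracle(a, b), abs=1e-12)

    def test_exact_close_to_normal_approximation_at_n8(self):
        rng = np.random.default_rng(88)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(0.5, 1.0, 8)
        exact = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        approx = stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic")
        assert exact.pvalue == pytest.approx(approx.pvalue, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


class TestCoV:
    def test_constant_values(self):
        assert coefficient_of_variation([2.0, 2.0, 2.0]) == 0.0

    def test_hand_computed_sample_sd(self):
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(DegenerateInputError):
            coefficient_of_variation([-1.0, 1.0])


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(5.0)
        assert correlation(x, 2 * x + 1) == pytest.approx(1.0)

    def test_perfect_inverse(self):
        x = np.arange(5.0)
        assert correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 40)
        y = 0.4 * x + rng.normal(0, 1, 40)
        oracle = (np.mean((x - x.mean()) * (y - y.mean()))
                  / (x.std() * y.std()))
        assert correlation(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _toy_table():
    rows = []
    for region, left, right in [("hippocampus", 1.0, 3.0), ("thalamus", 2.0, 2.0),
                                ("lateral ventricles", 9.0, 9.0)]:
        for side, value in (("left", left), ("right", right)):
            rows.append({"subject": "r1", "session": "baseline", "region": region,
                         "side": side, "model": "1TC", "metric": "V_T",
                         "value": value})
    return pd.DataFrame(rows)


class TestAggregateRegions:
    def test_mean_of_sides(self):
        out = aggregate_regions(_toy_table())
        hip = out[out["region"] == "hippocampus"]
        assert hip["mean"].iloc[0] == pytest.approx(2.0)

    def test_ventricles_excluded_by_default(self):
        out = aggregate_regions(_toy_table())
        assert "lateral ventricles" not in set(out["region"])

    def test_failed_fits_counted_not_averaged(self):
        df = pd.DataFrame([
            {"subject": s, "session": "baseline", "region": "hippocampus",
             "side": "left", "model": "1TC", "metric": "V_T", "value": v}
            for s, v in [("r1", 2.0), ("r2", np.nan), ("r3", 4.0)]])
        out = aggregate_regions(df, pairing="per-side")
        assert out["mean"].iloc[0] == pytest.approx(3.0)
        assert out["failures"].iloc[0] == 1
        assert out["n"].iloc[0] == 2

    def test_default_region_set_reduces_29_to_26(self):
        from petkin.simulate import SyntheticCohortSpec
        spec = SyntheticCohortSpec()
        labels = spec.regions
        assert len(labels) == 29
        df = pd.DataFrame([{"subject": "r1", "session": "baseline",
                            "region": r, "side": s, "model": "SUV",
                            "metric": "SUV", "value": 1.0}
                           for r, s in labels])
        out = aggregate_regions(df, pairing="per-side")
        assert len(out) == 26


class TestCompareSessions:
    def _cohort_table(self, effect=2.0, n=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            base = 1.0 + 0.1 * rng.normal()
            for session, mult in (("baseline", 1.0), ("D0+6", effect)):
                for side in ("left", "right"):
                    rows.append({"subject": f"r{i}", "session": session,
                                 "region": "hippocampus", "side": side,
                                 "model": "1TC", "metric": "V_T",
                                 "value": base * mult * (1 + 0.02 * rng.normal())})
        return pd.DataFrame(rows)

    def test_detects_large_effect_bilaterally(self):
        out = compare_sessions(self._cohort_table(), "baseline", "D0+6", alpha=0.01)
        row = out.iloc[0]
        assert row["bilateral_t"]
        assert row["percent_change"] == pytest.approx(100.0, abs=15.0)

    def test_null_effect_not_significant(self):
        out = compare_sessions(self._cohort_table(effect=1.0, seed=4),
                               "baseline", "D0+6", alpha=0.01)
        assert not out.iloc[0]["bilateral_t"]
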