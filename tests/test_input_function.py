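"""Input-function construction: parent fraction, plasma/blood ratio, AIF
assembly, SUV scaling, cross-session normalization and the mean AIF."""

import numpy as np
import pytest

from petkin.curves import InputFunction, SessionMeta
from petkin.exceptions import (DegenerateInputError, InsufficientDataError,
                               ValidationError)
from petkin.input_function import (BloodSampleSeries, ParentFractionModel,
                                   PlasmaOverBloodModel, build_aif,
                                   build_mean_aif, compute_suv,
                                   fit_parent_fraction, fit_plasma_over_blood,
                                   normalize_aif_to_session, suv_scale_factor)
from petkin.schedules import default_arterial_times, default_fine_grid
from petkin.simulate import true_parent_aif


def _series(times, blood=None, pf=None, plasma=None):
    times = np.asarray(times, dtype=float)
    return BloodSampleSeries(
        subject="r", session="D0+35", time_min=times,
        blood_kBq_per_mL=np.ones_like(times) if blood is None else np.asarray(blood, float),
        parent_fraction=pf if pf is None else np.asarray(pf, float),
        plasma_kBq_per_mL=plasma if plasma is None else np.asarray(plasma, float),
    )


class TestParentFraction:
    def test_all_unity_fractions_fit_constant_model(self):
        s = _series([5, 25, 40, 50], pf=[1.0, 1.0, 1.0, 1.0])
        model = fit_parent_fraction(s, begin=1.0)
        t = np.linspace(0, 60, 200)
        np.testing.assert_allclose(model(t), 1.0, atol=1e-9)

    def test_noiseless_refit_recovers_generating_model(self):
        gen = ParentFractionModel(begin=0.75, a1=0.6, b1=0.4, b2=0.02)
        times = np.array([5.0, 25.0, 40.0, 50.0])
        s = _series(times, pf=gen(times))
        refit = fit_parent_fraction(s, begin=0.75)
        assert abs(refit(np.array([50.0]))[0] - gen(np.array([50.0]))[0]) < 1e-3

    def test_plateau_is_exactly_one_before_begin(self):
        gen = ParentFractionModel(begin=0.75, a1=0.6, b1=0.4, b2=0.02)
        times = np.array([5.0, 25.0, 40.0, 50.0])
        refit = fit_parent_fraction(_series(times, pf=gen(times)), begin=0.75)
        assert refit(np.array([0.5]))[0] == 1.0
        assert refit(np.array([0.0]))[0] == 1.0

    def test_too_few_metabolite_samples_raises(self):
        s = _series([5, 25, 40, 50], pf=[0.8, np.nan, np.nan, np.nan])
        with pytest.raises(InsufficientDataError):
            fit_parent_fraction(s)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            _series([5, 25], pf=[1.2, 0.5])

    def test_model_invariants(self):
        m = ParentFractionModel(begin=0.75, a1=0.6, b1=0.4, b2=0.02)
        assert m.a1 + m.a2 == 1.0
        t = np.linspace(0, 60, 500)
        assert np.all((m(t) >= 0) & (m(t) <= 1))
        assert np.all(m(t[t <= 0.75]) == 1.0)


class TestPlasmaOverBlood:
    def test_constant_ratio(self):
        t = default_arterial_times()
        s = _series(t, blood=np.ones_like(t), plasma=1.3 * np.ones_like(t))
        m = fit_plasma_over_blood(s)
        assert m.intercept == pytest.approx(1.3, abs=1e-12)
        assert m.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_recovery(self):
        t = default_arterial_times()
        ratio = 1.1 + 0.004 * t
        s = _series(t, blood=2.0 * np.ones_like(t), plasma=2.0 * ratio)
        m = fit_plasma_over_blood(s)
        assert m.intercept == pytest.approx(1.1, abs=1e-9)
        assert m.slope == pytest.approx(0.004, abs=1e-9)

    def test_two_point_line(self):
        s = _series([1e-9, 50.0], blood=[1.0, 1.0], plasma=[1.0, 2.0])
        m = fit_plasma_over_blood(s)
        assert m.intercept == pytest.approx(1.0, abs=1e-7)
        assert m.slope == pytest.approx(0.02, abs=1e-9)

    def test_single_point_raises(self):
        t = default_arterial_times()
        plasma = np.full_like(t, np.nan)
        plasma[0] = 1.0
        with pytest.raises(InsufficientDataError):
            fit_plasma_over_blood(_series(t, plasma=plasma))

    def test_nonpositive_line_flagged(self):
        s = _series([1.0, 10.0], blood=[1.0, 1.0], plasma=[1.0, 0.1])
        assert fit_plasma_over_blood(s).nonpositive_warning


class TestBuildAif:
    def test_identity_pf_and_pob_returns_interpolated_blood(self):
        t = default_arterial_times()
        blood = 100.0 * np.exp(-0.05 * t)
        s = _series(t, blood=blood)
        pf = ParentFractionModel(begin=60.0, a1=1.0, b1=0.0, b2=0.0)  # pf == 1
        pob = PlasmaOverBloodModel(intercept=1.0, slope=0.0)
        aif = build_aif(s, pf, pob)
        expected = np.interp(aif.t_min, np.concatenate([[0.0], t]),
                             np.concatenate([[0.0], blood]))
        np.testing.assert_allclose(aif.plasma, expected, rtol=1e-12)

    def test_pointwise_arithmetic(self):
        # interpolated blood 50 at t=10, ratio 1.4, parent fraction 0.5
        s = _series([5.0, 15.0], blood=[50.0, 50.0])
        pf = ParentFractionModel(begin=0.0, a1=1.0, b1=np.log(2.0) / 10.0, b2=0.0)
        pob = PlasmaOverBloodModel(intercept=1.4, slope=0.0)
        aif = build_aif(s, pf, pob, grid=np.array([0.0, 10.0, 20.0]))
        assert aif.plasma[1] == pytest.approx(50.0 * 1.4 * 0.5, rel=1e-12)

    def test_rebuild_matches_generator_truth(self, blood_series, noiseless_spec):
        pf = fit_parent_fraction(blood_series)
        pob = fit_plasma_over_blood(blood_series)
        rebuilt = build_aif(blood_series, pf, pob)
        truth = true_parent_aif(noiseless_spec, "rat01", "D0+35")
        w = (rebuilt.t_min >= 1.0) & (rebuilt.t_min <= 60.0)
        rel_l2 = (np.linalg.norm(rebuilt.plasma[w] - truth.plasma[w])
                  / np.linalg.norm(truth.plasma[w]))
        assert rel_l2 < 0.05

    def test_aif_never_exceeds_total_plasma(self, blood_series):
        pf = fit_parent_fraction(blood_series)
        pob = fit_plasma_over_blood(blood_series)
        aif = build_aif(blood_series, pf, pob)
        plasma_total = aif.blood * pob(aif.t_min)
        assert np.all(aif.plasma <= plasma_total + 1e-12)
        early = aif.t_min <= pf.begin
        np.testing.assert_allclose(aif.plasma[early], plasma_total[early])

    def test_decreasing_grid_rejected(self, blood_series):
        pf = fit_parent_fraction(blood_series)
        pob = fit_plasma_over_blood(blood_series)
        with pytest.raises(ValidationError):
            build_aif(blood_series, pf, pob, grid=np.array([0.0, 2.0, 1.0]))


class TestSuv:
    def test_as_printed_arithmetic(self):
        assert compute_suv(9250.0, 37e6, 250.0) == pytest.approx(1.0e-6)

    def test_conventional_arithmetic(self):
        assert compute_suv(9250.0, 37e6, 250.0, convention="conventional") \
            == pytest.approx(0.0625)

    def test_zero_concentration(self):
        assert compute_suv(0.0, 37e6, 250.0) == 0.0
        assert compute_suv(0.0, 37e6, 250.0, convention="conventional") == 0.0

    @pytest.mark.parametrize("dose,weight", [(0.0, 250.0), (37e6, -1.0)])
    def test_nonpositive_dose_or_weight_rejected(self, dose, weight):
        with pytest.raises(ValidationError):
            compute_suv(1.0, dose, weight)

    @pytest.mark.parametrize("convention", ["as-printed", "conventional"])
    def test_session_suv_ratio_matches_normalization_scalar(self, convention):
        # if the AIF is SUV-invariant, rescaling by the normalization scalar
        # leaves the SUV unchanged under the matching convention
        m1 = SessionMeta(subject="r", session="baseline", dose_MBq=35.0, weight_g=240.0)
        m2 = SessionMeta(subject="r", session="D0+6", dose_MBq=39.0, weight_g=275.0)
        s = suv_scale_factor(m1, m2, convention)
        c1 = 5000.0
        suv1 = compute_suv(c1, m1.dose_Bq, m1.weight_g, convention)
        suv2 = compute_suv(c1 * s, m2.dose_Bq, m2.weight_g, convention)
        assert suv2 == pytest.approx(suv1, rel=1e-12)


class TestNormalizeAif:
    def _aif(self, meta=None):
        t = np.linspace(0.0, 60.0, 601)
        return InputFunction(t_min=t, plasma=100.0 * t * np.exp(-0.3 * t),
                             provenance="measured", meta=meta)

    def test_self_normalization_is_identity(self):
        m = SessionMeta(subject="r", session="D0+35", dose_MBq=37.0, weight_g=300.0)
        out = normalize_aif_to_session(self._aif(m), m, m)
        np.testing.assert_array_equal(out.plasma, self._aif(m).plasma)
        assert out.provenance == "session-derived"

    def test_proportional_scaling(self):
        m1 = SessionMeta(subject="r", session="D0+35", dose_MBq=40.0, weight_g=300.0)
        m2 = SessionMeta(subject="r", session="baseline", dose_MBq=40.0, weight_g=150.0)
        out = normalize_aif_to_session(self._aif(m1), m1, m2)
        np.testing.assert_allclose(out.plasma, 0.5 * self._aif(m1).plasma, rtol=1e-12)

    def test_group_action_composition(self):
        ms = [SessionMeta(subject="r", session=s, dose_MBq=d, weight_g=w)
              for s, d, w in (("baseline", 35.0, 240.0), ("D0+6", 38.5, 270.0),
                              ("D0+35", 36.2, 330.0))]
        a = self._aif(ms[0])
        via_b = normalize_aif_to_session(
            normalize_aif_to_session(a, ms[0], ms[1]).scaled(1.0, provenance="measured"),
            ms[1], ms[2])
        direct = normalize_aif_to_session(a, ms[0], ms[2])
        np.testing.assert_allclose(via_b.plasma, direct.plasma, rtol=1e-12)

    def test_cross_subject_measured_normalization_rejected(self):
        m1 = SessionMeta(subject="r1", session="D0+35", dose_MBq=37.0, weight_g=300.0)
        m2 = SessionMeta(subject="r2", session="D0+35", dose_MBq=37.0, weight_g=300.0)
        with pytest.raises(ValidationError):
            normalize_aif_to_session(self._aif(m1), m1, m2)

    def test_derived_session_aif_matches_generator_truth(self, noiseless_spec):
        # the generator makes each subject's sessions exact SUV-scaled copies
        src = true_parent_aif(noiseless_spec, "rat01", "D0+35")
        derived = normalize_aif_to_session(src, src.meta,
                                           true_parent_aif(noiseless_spec, "rat01",
                                                           "D0+6").meta)
        truth = true_parent_aif(noiseless_spec, "rat01", "D0+6")
        rel_l2 = np.linalg.norm(derived.plasma - truth.plasma) \
            / np.linalg.norm(truth.plasma)
        assert rel_l2 < 0.01


class TestMeanAif:
    def _measured(self, scale=1.0):
        t = default_fine_grid()
        return InputFunction(t_min=t, plasma=scale * 80.0 * t * np.exp(-0.4 * t),
                             provenance="measured")

    def _metas(self, n):
        return [SessionMeta(subject=f"r{i}", session="D0+35",
                            dose_MBq=35.0 + i, weight_g=300.0 + 5 * i)
                for i in range(n)]

    def test_identical_inputs_reproduced(self):
        aifs = [self._measured() for _ in range(4)]
        mean = build_mean_aif(aifs, self._metas(4))
        np.testing.assert_allclose(mean.plasma, aifs[0].plasma, atol=1e-9)
        assert mean.provenance == "mean-derived"

    def test_scalar_multiples_preserve_shape(self):
        aifs = [self._measured(1.0), self._measured(3.0)]
        mean = build_mean_aif(aifs, self._metas(2))
        ratio = mean.plasma[1:] / aifs[0].plasma[1:]
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_amplitude_jitter_mean_matches_template_shape(self):
        rng = np.random.default_rng(7)
        scales = np.exp(rng.normal(0.0, 0.10, size=7))
        aifs = [self._measured(s) for s in scales]
        mean = build_mean_aif(aifs, self._metas(7))
        norm = lambda p: (p - p.min()) / (p.max() - p.min())
        assert np.max(np.abs(norm(mean.plasma) - norm(aifs[0].plasma))) < 0.02

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        scales = np.exp(rng.normal(0.0, 0.1, size=5))
        aifs = [self._measured(s) for s in scales]
        metas = self._metas(5)
        mean1 = build_mean_aif(aifs, metas)
        order = [3, 1, 4, 0, 2]
        mean2 = build_mean_aif([aifs[i] for i in order], [metas[i] for i in order])
        np.testing.assert_allclose(mean1.plasma, mean2.plasma, atol=1e-12)
        assert mean1.meta.dose_MBq == pytest.approx(mean2.meta.dose_MBq)

    def test_single_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            build_mean_aif([self._measured()], self._metas(1))

    def test_flat_aif_rejected(self):
        t = default_fine_grid()
        flat = InputFunction(t_min=t, plasma=np.zeros_like(t), provenance="measured")
        with pytest.raises(DegenerateInputError):
            build_mean_aif([flat, self._measured()], self._metas(2))
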