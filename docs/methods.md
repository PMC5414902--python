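# Methods

This note documents the models implemented in `petkin`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the package's numerical choices and known limitations.

## Input functions

**Blood sampling model.** A session with arterial sampling provides 13
samples (3, 10, 20, 30, 40, 50 s; 1, 2, 5, 10, 25, 40, 50 min), four of
which (5, 25, 40, 50 min) carry a measured plasma parent fraction. Three
fitted components turn these into a continuous metabolite-corrected input:

1. *Plasma-over-blood ratio*: an ordinary least-squares straight line
   α + βt through the per-sample plasma/whole-blood activity ratios. A
   fitted line that goes non-positive anywhere in [0, 60] min sets a
   warning flag; evaluation at build time errors instead of producing
   negative plasma.
2. *Parent fraction*: pf(t) = 1 for t ≤ *Begin* and
   a₁e^(−b₁(t−Begin)) + a₂e^(−b₂(t−Begin)) beyond it, with a₁ + a₂ = 1
   enforcing continuity at the plateau and b₁, b₂ ≥ 0. The constraint
   a₁ ∈ [0, 1] keeps pf within [0, 1]. Default *Begin* = 0.75 min: after
   the last early sample (50 s) and well before the first metabolite
   sample; configurable. The fit is a bounded least squares restarted
   from several rate splits, including the all-zero-rate start so a
   metabolite-free tracer fits exactly.
3. *Whole-blood curve*: piecewise-linear interpolation of the samples,
   anchored at (0, 0) and held flat beyond the last sample — the simplest
   defensible scheme for sparse late samples.

The AIF is blood(t) × pob(t) × pf(t) on a fine uniform grid, 1 s spacing
on [0, 60] min by default (resolving the 20 s early frames).

**Cross-session derivation.** Only the last session is sampled. Earlier
sessions receive the measured AIF rescaled by the scalar implied by
assuming the AIF is invariant *in SUV units* across a subject's sessions.
Two SUV conventions are provided and the scalar follows the configured
one: the `as-printed` convention divides activity by dose × weight (so
the scalar is the dose·weight ratio of the sessions); `conventional` is
the textbook SUV (activity × weight / dose). `as-printed` is the default;
neither is asserted as correct, and the switch changes the derived-AIF
scaling only when weights differ between sessions. A time-varying reading
of the session-SUV ratio would be circular (it divides the unknown AIF by
itself), so the scalar reading is the one implemented.

**Mean AIF.** The measured AIFs are resampled to the common grid, min–max
rescaled to [0, 1], averaged pointwise, and restored to concentration
units with the mean of the individual (max − min) amplitudes; the mean
dose and mean weight are attached so the mean AIF can be renormalized to
any session. The amplitude-restoration recipe is one deterministic,
dimensionally consistent choice among several; shape averaging is exact
when the inputs differ only by scale.

## Kinetic models

All models consume frame-averaged data: model curves are integrated over
each frame interval (trapezoid on the fine grid) rather than sampled at
mid-times, because the three 900 s late frames make mid-time sampling
inaccurate. Convolutions with e^(−kt) use a recursion that is exact for
piecewise-linear inputs on a uniform grid (evaluated as a linear filter),
which matches a stiff ODE integration to ~1e-8 relative error.

* **1TC** — weighted nonlinear least squares over (K1, k2), bounds
  K1 ∈ [0, 10] mL·cm⁻³·min⁻¹, k2 ∈ [1e-4, 10] min⁻¹, five log-spaced k2
  starts; V_T = K1/k2 with a delta-method standard error. Default weights
  are proportional to frame duration (the standard proxy for count
  statistics in decay-corrected data); uniform weights by option.
* **2TC** — four free rates, V_T = (K1/k2)(1 + k3/k4). This model class
  is fragile on noisy small-animal TACs, so results are *flagged* failed
  (never raised) on non-convergence, boundary-pinned rates, or a relative
  V_T standard error above 100%.
* **Logan plot** — OLS of ∫C_T/C_T against ∫C_p/C_T over frames with
  mid-time ≥ t*; slope = V_T, intercept reported as a diagnostic
  (−1/k2 for one-tissue kinetics). Default t* = 15 min (three late
  frames), configurable. Plasma integrals are trapezoid on the fine grid;
  tissue integrals are trapezoid over frame mid-times anchored at (0, 0).
  Non-positive tissue frames in the window are dropped with a warning;
  fewer than three remaining points flags failure.
* **Logan reference** — same linearization with
  (∫C_ref + C_ref/k2′)/C_T as abscissa; slope = DVR, BP_ND = DVR − 1.
  When k2′ is omitted the C_ref/k2′ term is dropped (late-time
  approximation) and flagged. The pipeline default derives k2′ per
  session as the median reference-region efflux (k2/R1) from SRTM fits
  of the reference region's left side against its right and vice versa.
* **SRTM** — basis functions over a log-spaced k2a grid (100 values,
  0.006–0.6 min⁻¹), linear weighted least squares per basis, followed by
  a continuous bounded refinement of k2a between the neighbouring grid
  points. The reference's instantaneous curve is reconstructed from its
  frame averages by iterative proportional correction until the
  reconstruction's own frame averages match the data (plain mid-time
  interpolation biases BP_ND by roughly −9% on this frame schedule). A
  best basis at the grid edge sets a warning flag. BP_ND may be negative
  (target binding below the reference); DVR = BP_ND + 1 is used for
  summaries.
* **SUV** — frame-duration-weighted mean concentration over a window
  (default the full 0–60 min, configurable, e.g. 30–60 min) scaled by the
  configured SUV convention.

No vascular blood-volume term is included by default (v_B = 0); the
companion whole-blood curve is carried so a fixed-v_B variant remains
possible. All activities are assumed decay-corrected to injection time.

## Group analysis

Session contrasts use a paired t test (primary) and a Mann–Whitney U test
(robustness check, applied to the same paired sessions as independent
groups — deliberately mirroring the study convention it reproduces). The
U test uses the exact enumeration null when the smaller group has ≤ 8
tie-free observations, and the tie-corrected normal approximation
otherwise. A bilateral structure counts as changed only when both sides
are significant, with strict inequality at the boundary. Percent changes
are relative to the earlier session; reports may print decrease
magnitudes. Coefficients of variation (100·sd/mean, n−1) carry a ≥ 20%
qualitative flag. Correlations are Pearson product-moment. No
multiple-testing correction is applied by default (per-region p-values
are reported as-is); a Bonferroni switch exists. Failed fits enter
summaries as missing values with a failure count, excluded listwise per
comparison.

## Synthetic cohorts

The generator emulates the study design end to end: 9 subjects × 3
sessions (baseline, day 6, day 35), 13 bilateral tissue structures (26
labels) plus 3 ventricle labels, the 20-frame schedule and both blood
sampling schedules, with blood tables only for the last session of 7 of
the 9 subjects.

* **Kinetic truth** is one-tissue per region: K1 = 0.1 mL·cm⁻³·min⁻¹
  fixed, k2 = K1/V_T. Baseline V_T = 1.0 (arbitrary units; no absolute
  levels are asserted, so percent-change targets are convention-level),
  ventricles 0.3. Day-6 multipliers: hippocampus ×2.18, amygdala ×1.86,
  temporal cortex ×1.94, thalamus ×1.79, brainstem ×1.17, frontal cortex
  ×1.35, other tissue ×1.50. Day-35 multipliers apply the matching
  partial-return decreases (53/44/47/44/31% from day 6 for the five named
  regions). The brainstem multiplier is the closest to 1 among tissue
  regions, preserving its role as reference region.
* **Plasma template**: linear rise to a 60 kBq/mL peak at 0.5 min, then a
  tri-exponential decay with fractions (0.70, 0.25, 0.05) and rates
  (8.0, 0.20, 0.015) min⁻¹ — a fast distribution phase essentially
  complete within the densely sampled first minute, so that the 13-point
  schedule resolves the curve (rebuild error < 5% relative L2 over
  [1, 60] min). Parent-fraction truth: Begin 0.75 min, a₁ = 0.6,
  b₁ = 0.4, b₂ = 0.02 min⁻¹; plasma-over-blood truth: 1.1 + 0.004t.
* **Between-subject structure**: a per-subject lognormal V_T factor
  (σ = 10%, giving baseline inter-subject CoV < 20%) and an independent
  per-subject lognormal AIF amplitude factor (σ = 10%). Session plasma
  curves are exact SUV-scaled copies of the template (dose ~ N(37, 2.5)
  MBq; weights growing 244 → 272 → 330 g with 5% subject jitter), so the
  cross-session derivation assumption holds exactly in the truth.
* **Noise**: independent Gaussian per frame, sd = CoV × frame value
  (default CoV 5%), clamped at zero. Everything derives deterministically
  from the spec seed; per-region noise streams are independent so any
  subset regenerates identically.

What the generator does **not** emulate — and what passing tests
therefore cannot show about real data: count-statistics noise scaling
with frame duration and decay, partial-volume and spill-over effects,
blood-sample measurement error, AIF shape differences between sessions
(dispersion, anesthesia effects), violations of the one-tissue assumption,
and region segmentation error. In particular, because each subject's
sessions share an exactly SUV-invariant plasma shape and an exact
within-subject V_T ratio, within-subject contrasts on synthetic cohorts
are *more* detectable than in reality: with 5% frame noise the V_T
estimators carry only ~2% error, so a paired t test detects even the
brainstem's +17% essentially always at α = 0.01, whereas the unpaired
Mann–Whitney check (which does not cancel the 10% between-subject spread)
flags the brainstem bilaterally in well under half of replicate cohorts.
The acceptance report states both rates.

## Problem sizes and numerical choices

The acceptance script scales replicate counts for a single-CPU desk run:
the noiseless 1TC recovery sweep uses a 3-subject sub-cohort (522 fits),
Monte-Carlo noise uses 200 replicates, percent-change estimates average
10 replicate cohorts of the 7 sampled subjects, detection rates use 50
effect cohorts, and null-cohort calibration uses 200 replicates; the test
suite runs the same checks at up to 100 effect and 500 null replicates.
Detection-rate checks quantify V_T by Logan plot (deterministic and fast)
on AIFs rebuilt from the generated blood tables; null-cohort calibration
uses the SUV arm, which involves no iterative fitting. Ties in the
k2a/basis search break toward the smaller WRSS first encountered
(deterministic grid order). Degenerate inputs (all-zero TACs, flat AIFs,
zero-variance differences) are flagged or rejected explicitly rather than
propagated as NaNs.

## Known limitations

* Region-of-interest level only: no voxelwise parametric imaging, no
  image I/O (tables are the interchange format), no partial-volume
  correction.
* No dispersion/delay correction of the AIF and no plasma free-fraction
  handling.
* The 2TC implementation is intentionally conservative in flagging; its
  estimates should not be used where the flags indicate failure.
* The exact Mann–Whitney switch requires tie-free data; tied data falls
  back to the corrected normal approximation even for small samples.
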