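"""Synthetic longitudinal TSPO-PET cohort generator.

Emulates the design of a pilocarpine status-epilepticus rat study: nine
subjects scanned at baseline, day 6 and day 35 post-insult; 29 atlas
labels (13 bilateral tissue regions plus 3 ventricle labels); the 20-frame
60-minute acquisition; 13 arterial samples with a 4-sample metabolite
subset at the last session of 7 of the 9 subjects.

Ground truth is one-tissue kinetics per region with K1 fixed and
k2 = K1 / V_T; day-6 V_T multipliers default to roughly two-fold increases
in temporal/limbic structures and a near-unchanged brainstem, with a
partial return toward baseline at day 35.  The plasma input is a shared
template (linear rise, tri-exponential decay) scaled per session so that
it is exactly invariant in SUV units across a subject's sessions, times a
per-subject lognormal amplitude factor.  Metabolite loss is a plateau-
then-biexponential parent fraction; the plasma-over-blood ratio is linear
in time.  Frame noise is independent Gaussian with standard deviation
proportional to the frame value, clamped at zero.

Everything is deterministic given the spec's seed: per-subject and
per-session random streams are derived from (seed, subject index,
session index), so any session can be regenerated in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .curves import InputFunction, SessionMeta, TimeActivityCurve
from .exceptions import ValidationError
from .input_function import ParentFractionModel, PlasmaOverBloodModel
from .kinetics.onetissue import solve_1tc_tac
from .schedules import (default_arterial_times, default_fine_grid,
                        default_frame_schedule, default_metabolite_times,
                        default_schedules)

__all__ = [
    "AifTemplateParams", "SyntheticCohortSpec", "CohortBundle", "SessionData",
    "make_template_aif", "generate_session", "generate_cohort",
    "true_parent_aif", "default_schedules",
    "TISSUE_REGIONS", "VENTRICLE_REGIONS",
]

SESSIONS = ("baseline", "D0+6", "D0+35")

#: 13 bilateral tissue structures (26 left/right labels).
TISSUE_REGIONS: Tuple[str, ...] = (
    "hippocampus", "amygdala", "temporal cortex", "thalamus",
    "frontal cortex", "parietal cortex", "occipital cortex",
    "cingulate cortex", "striatum", "hypothalamus", "septum",
    "brainstem", "cerebellum",
)

#: 3 unpaired ventricle labels (excluded from tissue summaries).
VENTRICLE_REGIONS: Tuple[str, ...] = (
    "lateral ventricles", "third ventricle", "fourth ventricle",
)


def _default_multipliers() -> Dict[str, Dict[str, float]]:
    """Per-region true V_T multipliers relative to baseline.

    Day-6 values for the four target regions and the brainstem encode
    increases of 118/86/94/79/17 %; day-35 values apply the matching
    decreases (53/44/47/44/31 % relative to day 6).  Unlisted tissue
    regions get a moderate generic response; ventricles do not respond.
    """
    named = {
        "hippocampus": (2.18, 2.18 * (1 - 0.53)),
        "amygdala": (1.86, 1.86 * (1 - 0.44)),
        "temporal cortex": (1.94, 1.94 * (1 - 0.47)),
        "thalamus": (1.79, 1.79 * (1 - 0.44)),
        "brainstem": (1.17, 1.17 * (1 - 0.31)),
        "frontal cortex": (1.35, 1.00),
    }
    out: Dict[str, Dict[str, float]] = {}
    for region in TISSUE_REGIONS:
        d6, d35 = named.get(region, (1.50, 1.10))
        out[region] = {"baseline": 1.0, "D0+6": d6, "D0+35": d35}
    for region in VENTRICLE_REGIONS:
        out[region] = {"baseline": 1.0, "D0+6": 1.0, "D0+35": 1.0}
    return out


@dataclass(frozen=True)
class AifTemplateParams:
    """Parametric plasma template: linear rise to a peak, tri-exponential decay.

    Amplitude is the peak total-plasma activity (kBq/mL) at the reference
    dose and weight; fractions sum to 1 and rates are per-minute.
    """

    amplitude: float = 60.0
    t_peak_min: float = 0.5
    fractions: Tuple[float, float, float] = (0.70, 0.25, 0.05)
    rates_per_min: Tuple[float, float, float] = (8.0, 0.20, 0.015)

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.t_peak_min <= 0:
            raise ValidationError("template amplitude must be >= 0 and t_peak > 0")
        if any(f < 0 for f in self.fractions) or any(r < 0 for r in self.rates_per_min):
            raise ValidationError("template fractions and rates must be >= 0")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Complete ground-truth description of a synthetic cohort."""

    n_subjects: int = 9
    n_with_blood: int = 7
    sessions: Tuple[str, ...] = SESSIONS
    baseline_vt: float = 1.0
    ventricle_vt: float = 0.3
    K1: float = 0.1
    vt_multipliers: Dict[str, Dict[str, float]] = field(default_factory=_default_multipliers)
    subject_vt_sigma: float = 0.10     # lognormal sd of the per-subject baseline V_T factor
    aif_amp_sigma: float = 0.10        # lognormal sd of the per-subject AIF amplitude
    noise_cov: float = 0.05            # Gaussian frame noise, sd = cov x value
    dose_mean_MBq: float = 37.0
    dose_sigma_MBq: float = 2.5
    weight_means_g: Dict[str, float] = field(default_factory=lambda: {
        "baseline": 244.0, "D0+6": 272.0, "D0+35": 330.0})
    weight_sigma_frac: float = 0.05
    template: AifTemplateParams = field(default_factory=AifTemplateParams)
    pf_begin_min: float = 0.75
    pf_a1: float = 0.6
    pf_b1: float = 0.4
    pf_b2: float = 0.02
    pob_intercept: float = 1.1
    pob_slope: float = 0.004
    grid_dt_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_with_blood <= self.n_subjects:
            raise ValidationError("n_with_blood must be in (0, n_subjects]")
        for region, m in self.vt_multipliers.items():
            if any(v <= 0 for v in m.values()):
                raise ValidationError(f"V_T multipliers must be > 0 ({region})")

    @property
    def subjects(self) -> Tuple[str, ...]:
        return tuple(f"rat{str(i + 1).zfill(2)}" for i in range(self.n_subjects))

    @property
    def subjects_with_blood(self) -> Tuple[str, ...]:
        return self.subjects[: self.n_with_blood]

    @property
    def regions(self) -> Tuple[Tuple[str, str], ...]:
        """(region, side) labels: 26 paired tissue + 3 unpaired ventricle = 29."""
        pairs = [(r, s) for r in TISSUE_REGIONS for s in ("left", "right")]
        pairs += [(r, "unpaired") for r in VENTRICLE_REGIONS]
        return tuple(pairs)

    def parent_fraction_model(self) -> ParentFractionModel:
        return ParentFractionModel(begin=self.pf_begin_min, a1=self.pf_a1,
                                   b1=self.pf_b1, b2=self.pf_b2)

    def plasma_over_blood_model(self) -> PlasmaOverBloodModel:
        return PlasmaOverBloodModel(intercept=self.pob_intercept, slope=self.pob_slope)

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)

    def spec_hash(self) -> str:
        return hashlib.md5(self.canonical_json().encode()).hexdigest()


def make_template_aif(params: AifTemplateParams,
                      grid: Optional[np.ndarray] = None) -> InputFunction:
    """Evaluate the plasma template on a grid: 0 at t=0, linear rise to the
    peak at t_peak, then a tri-exponential decay."""
    if grid is None:
        grid = default_fine_grid()
    grid = np.asarray(grid, dtype=float)
    fsum = sum(params.fractions)
    decay = sum(f / fsum * np.exp(-r * np.maximum(grid - params.t_peak_min, 0.0))
                for f, r in zip(params.fractions, params.rates_per_min))
    rise = np.clip(grid / params.t_peak_min, 0.0, 1.0)
    curve = params.amplitude * rise * np.where(grid <= params.t_peak_min, 1.0, decay)
    return InputFunction(t_min=grid, plasma=curve, provenance="measured")


# --- deterministic per-subject / per-session random draws -------------------

def _subject_rng(spec: SyntheticCohortSpec, subj_idx: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 1000 + subj_idx])


def _subject_factors(spec: SyntheticCohortSpec, subj_idx: int):
    rng = _subject_rng(spec, subj_idx)
    vt_factor = float(np.exp(rng.normal(0.0, spec.subject_vt_sigma)))
    amp_factor = float(np.exp(rng.normal(0.0, spec.aif_amp_sigma)))
    weight_factor = float(max(rng.normal(1.0, spec.weight_sigma_frac), 0.5))
    return vt_factor, amp_factor, weight_factor


def _session_meta(spec: SyntheticCohortSpec, subj_idx: int, session: str) -> SessionMeta:
    sess_idx = list(spec.sessions).index(session)
    _, _, weight_factor = _subject_factors(spec, subj_idx)
    rng = np.random.default_rng([spec.seed, 3000 + subj_idx, sess_idx])
    dose = float(max(rng.normal(spec.dose_mean_MBq, spec.dose_sigma_MBq), 1.0))
    weight = spec.weight_means_g[session] * weight_factor
    return SessionMeta(subject=spec.subjects[subj_idx], session=session,
                       dose_MBq=dose, weight_g=weight)


def _aif_scale(spec: SyntheticCohortSpec, subj_idx: int, meta: SessionMeta) -> float:
    """Session plasma amplitude relative to the template reference.

    The template is defined at the reference dose/weight (cohort means);
    scaling by dose x weight makes the AIF exactly SUV-invariant (in the
    as-printed convention) across a subject's sessions.
    """
    _, amp_factor, _ = _subject_factors(spec, subj_idx)
    ref = spec.dose_mean_MBq * spec.weight_means_g["baseline"]
    return amp_factor * (meta.dose_MBq * meta.weight_g) / ref


def true_parent_aif(spec: SyntheticCohortSpec, subject: str, session: str,
                    grid: Optional[np.ndarray] = None) -> InputFunction:
    """Ground-truth metabolite-corrected parent plasma input for a session."""
    subj_idx = spec.subjects.index(subject)
    if grid is None:
        grid = default_fine_grid(dt_s=spec.grid_dt_s)
    meta = _session_meta(spec, subj_idx, session)
    scale = _aif_scale(spec, subj_idx, meta)
    template = make_template_aif(spec.template, grid)
    plasma_total = template.plasma * scale
    pf = spec.parent_fraction_model()
    pob = spec.plasma_over_blood_model()
    return InputFunction(t_min=grid, plasma=plasma_total * pf(grid),
                         blood=plasma_total / pob(grid),
                         provenance="measured", meta=meta)


@dataclass
class SessionData:
    """One generated subject/session: samples, TACs, metadata, ground truth."""

    meta: SessionMeta
    tacs: List[TimeActivityCurve]
    blood_time_min: np.ndarray
    blood_kBq_per_mL: np.ndarray
    plasma_kBq_per_mL: np.ndarray
    parent_fraction: np.ndarray  # NaN outside the metabolite subset
    truth: Dict


def generate_session(spec: SyntheticCohortSpec, subject: str, session: str,
                     rng: Optional[np.random.Generator] = None,
                     regions: Optional[Tuple[str, ...]] = None) -> SessionData:
    """Generate one subject/session (blood samples, regional TACs, truth).

    ``rng`` drives the frame noise only; when omitted it is derived from
    (spec.seed, subject, session) so isolated regeneration is reproducible.
    ``regions`` restricts generation to the named regions (all by default);
    with the default rng the noise stream of each region label is derived
    independently, so a restricted call reproduces the same TACs as the
    full one.
    """
    if subject not in spec.subjects or session not in spec.sessions:
        raise ValidationError(f"unknown subject/session {subject}/{session}")
    subj_idx = spec.subjects.index(subject)
    sess_idx = list(spec.sessions).index(session)

    schedule = default_frame_schedule()
    grid = default_fine_grid(dt_s=spec.grid_dt_s)
    aif = true_parent_aif(spec, subject, session, grid)
    meta = aif.meta
    pf = spec.parent_fraction_model()
    pob = spec.plasma_over_blood_model()

    # arterial samples read off the true curves
    t_samp = default_arterial_times()
    plasma_total = aif.blood * pob(grid)  # blood stores total plasma / pob
    blood_samp = np.interp(t_samp, grid, aif.blood)
    plasma_samp = np.interp(t_samp, grid, plasma_total)
    pf_samp = np.full_like(t_samp, np.nan)
    met_mask = np.isin(t_samp, default_metabolite_times())
    pf_samp[met_mask] = pf(t_samp[met_mask])

    vt_factor, _, _ = _subject_factors(spec, subj_idx)
    tacs: List[TimeActivityCurve] = []
    vt_truth: Dict[str, float] = {}
    for i, (region, side) in enumerate(spec.regions):
        if regions is not None and region not in regions:
            continue
        base = spec.ventricle_vt if region in VENTRICLE_REGIONS else spec.baseline_vt
        vt_true = base * vt_factor * spec.vt_multipliers[region][session]
        k2 = spec.K1 / vt_true
        tac = solve_1tc_tac(spec.K1, k2, aif, schedule,
                            subject=subject, session=session,
                            region=region, side=side)
        values = tac.values
        if spec.noise_cov > 0:
            region_rng = (np.random.default_rng([spec.seed, 2000 + subj_idx,
                                                 sess_idx, i])
                          if rng is None else rng)
            noise = region_rng.normal(0.0, spec.noise_cov * np.abs(values))
            values = np.maximum(values + noise, 0.0)
            tac = TimeActivityCurve(subject=subject, session=session,
                                    region=region, side=side,
                                    schedule=schedule, values=values,
                                    noise_flag=True)
        tacs.append(tac)
        vt_truth[f"{region}|{side}"] = vt_true

    truth = {
        "subject": subject,
        "session": session,
        "dose_MBq": meta.dose_MBq,
        "weight_g": meta.weight_g,
        "aif_scale": _aif_scale(spec, subj_idx, meta),
        "K1": spec.K1,
        "vt_true": vt_truth,
    }
    return SessionData(meta=meta, tacs=tacs,
                       blood_time_min=t_samp, blood_kBq_per_mL=blood_samp,
                       plasma_kBq_per_mL=plasma_samp, parent_fraction=pf_samp,
                       truth=truth)


@dataclass
class CohortBundle:
    """Full cohort as long-format tables plus truth and manifest records."""

    tacs: "pd.DataFrame"
    blood: "pd.DataFrame"
    sessions: "pd.DataFrame"
    truth: Dict
    manifest: Dict


def generate_cohort(spec: SyntheticCohortSpec,
                    out_dir: Optional[str] = None,
                    overwrite: bool = False) -> CohortBundle:
    """Generate the whole cohort; optionally write the file bundle.

    Blood tables are produced only for the last session of the subjects
    flagged as having arterial sampling (default 7 of 9); the remaining
    subjects exercise the reference-region-only analysis paths.
    """
    import pandas as pd

    schedule = default_frame_schedule()
    tac_rows, blood_rows, sess_rows = [], [], []
    truth: Dict = {
        "spec_hash": spec.spec_hash(),
        "seed": spec.seed,
        "template": asdict(spec.template),
        "parent_fraction": {"begin": spec.pf_begin_min, "a1": spec.pf_a1,
                            "b1": spec.pf_b1, "b2": spec.pf_b2},
        "plasma_over_blood": {"intercept": spec.pob_intercept,
                              "slope": spec.pob_slope},
        "sessions": [],
    }
    for subject in spec.subjects:
        for session in spec.sessions:
            data = generate_session(spec, subject, session)
            truth["sessions"].append(data.truth)
            sess_rows.append({"subject": subject, "session": session,
                              "dose_MBq": data.meta.dose_MBq,
                              "weight_g": data.meta.weight_g})
            for tac in data.tacs:
                for j in range(schedule.n_frames):
                    tac_rows.append({
                        "subject": subject, "session": session,
                        "region": tac.region, "side": tac.side,
                        "frame_start_s": schedule.start_s[j],
                        "frame_end_s": schedule.end_s[j],
                        "kBq_per_mL": tac.values[j],
                    })
            if subject in spec.subjects_with_blood and session == spec.sessions[-1]:
                for i, t in enumerate(data.blood_time_min):
                    blood_rows.append({
                        "subject": subject, "session": session,
                        "time_min": t,
                        "blood_kBq_per_mL": data.blood_kBq_per_mL[i],
                        "plasma_kBq_per_mL": data.plasma_kBq_per_mL[i],
                        "parent_fraction": data.parent_fraction[i],
                    })

    manifest = {
        "seed": spec.seed,
        "spec_hash": spec.spec_hash(),
        "n_subjects": spec.n_subjects,
        "sessions": list(spec.sessions),
        "subjects": list(spec.subjects),
        "subjects_with_blood": list(spec.subjects_with_blood),
        "n_region_labels": len(spec.regions),
        "n_tissue_regions": sum(1 for r, _ in spec.regions
                                if r not in VENTRICLE_REGIONS),
    }
    bundle = CohortBundle(
        tacs=pd.DataFrame(tac_rows),
        blood=pd.DataFrame(blood_rows),
        sessions=pd.DataFrame(sess_rows),
        truth=truth,
        manifest=manifest,
    )
    if out_dir is not None:
        from .io import write_cohort_bundle
        write_cohort_bundle(bundle, out_dir, overwrite=overwrite)
    return bundle
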