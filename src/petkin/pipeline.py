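"""End-to-end study workflow: tables in, per-region results and group reports out.

For every subject with arterial sampling the measured last-session AIF is
built from the blood table (ratio line + parent-fraction fit), and the
earlier sessions receive dose/weight-normalized derived AIFs.  A cohort
mean AIF is built from all measured AIFs and can drive an additional
1TC arm for every subject, including those without blood sampling.
Per-fit failures are recorded in the results table, never raised, so a
cohort run always completes.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import StudyConfig
from .curves import InputFunction, SessionMeta, TimeActivityCurve
from .exceptions import ConfigError, ValidationError
from .group_analysis import aggregate_regions, compare_sessions
from .input_function import (build_aif, build_mean_aif, fit_parent_fraction,
                             fit_plasma_over_blood, normalize_aif_to_session)
from .io import read_tables
from .kinetics import (LoganPlot, LoganReference, OneTissueModel, SRTM,
                       TwoTissueModel, suv_summary)

__all__ = ["run_pipeline", "PipelineReport", "SESSION_ORDER"]

SESSION_ORDER = ("baseline", "D0+6", "D0+35")
AIF_MODELS = {"LP", "1TC", "2TC"}


@dataclass
class PipelineReport:
    """Everything a pipeline run produces, in memory."""

    results: pd.DataFrame
    group_summary: pd.DataFrame
    comparisons: pd.DataFrame
    aifs: Dict[Tuple[str, str], InputFunction]
    mean_aif: Optional[InputFunction]
    log: List[str] = field(default_factory=list)


def _metric_rows(res, model: str) -> List[dict]:
    """Long-format metric rows (one per macro-parameter) for one fit."""
    base = res.to_row()
    rows = []
    if base.get("V_T") is not None or model in AIF_MODELS or model == "1TC-mAIF":
        rows.append({**base, "metric": "V_T",
                     "value": base.get("V_T") if not res.failed else np.nan})
    if res.bp_nd is not None or model in ("LR", "SRTM"):
        rows.append({**base, "metric": "BP_ND",
                     "value": res.bp_nd if not res.failed else np.nan})
        rows.append({**base, "metric": "DVR",
                     "value": res.dvr if not res.failed else np.nan})
    return rows


def _reference_tac(tacs_by_key, subject: str, session: str,
                   region: str) -> Optional[TimeActivityCurve]:
    """Reference curve: mean of the left/right reference-region TACs."""
    sides = [tacs_by_key.get((subject, session, region, s))
             for s in ("left", "right")]
    sides = [t for t in sides if t is not None]
    unpaired = tacs_by_key.get((subject, session, region, "unpaired"))
    if unpaired is not None:
        sides.append(unpaired)
    if not sides:
        return None
    values = np.mean([t.values for t in sides], axis=0)
    return TimeActivityCurve(subject=subject, session=session, region=region,
                             side="unpaired", schedule=sides[0].schedule,
                             values=values, noise_flag=True)


def _session_k2_prime(tacs_by_key, subject: str, session: str,
                      region: str) -> Optional[float]:
    """k2' from the reference region's contralateral SRTM pairings.

    Fits left-vs-right and right-vs-left SRTM within the reference region
    and takes the median of k2/R1 (the reference efflux rate implied by
    each fit)."""
    left = tacs_by_key.get((subject, session, region, "left"))
    right = tacs_by_key.get((subject, session, region, "right"))
    if left is None or right is None:
        return None
    estimates = []
    for target, ref in ((left, right), (right, left)):
        try:
            res = SRTM(target, ref).fit()
        except ValidationError:
            continue
        r1 = res.params.get("R1", 0.0)
        if not res.failed and r1 > 0:
            estimates.append(res.params["k2"] / r1)
    return float(np.median(estimates)) if estimates else None


def run_pipeline(config: StudyConfig) -> PipelineReport:
    """Run the configured quantification arms over the whole cohort."""
    tacs, blood_list, metas = read_tables(config.tac_table, config.blood_table,
                                          config.sessions_table)
    log: List[str] = [f"config_hash={_config_hash(config)} seed={config.seed}"]
    meta_by_key = {(m.subject, m.session): m for m in metas}
    tacs_by_key = {(t.subject, t.session, t.region, t.side): t for t in tacs}
    subjects = sorted({t.subject for t in tacs})
    sessions = [s for s in SESSION_ORDER if any(t.session == s for t in tacs)]

    wants_aif = bool(AIF_MODELS & set(config.models))
    wants_mean = "1TC-mAIF" in config.models
    if (wants_aif or wants_mean) and not blood_list:
        raise ConfigError("AIF-based models requested but no blood table given")

    # --- measured AIFs and derived earlier-session AIFs ---------------------
    aifs: Dict[Tuple[str, str], InputFunction] = {}
    measured: List[InputFunction] = []
    measured_metas: List[SessionMeta] = []
    for samples in blood_list:
        key = (samples.subject, samples.session)
        if key not in meta_by_key:
            raise ValidationError(f"no session metadata for blood table {key}")
        pf = fit_parent_fraction(samples)
        pob = fit_plasma_over_blood(samples)
        aif = build_aif(samples, pf, pob, meta=meta_by_key[key])
        aifs[key] = aif
        measured.append(aif)
        measured_metas.append(meta_by_key[key])
        log.append(f"AIF built for {key[0]}/{key[1]} "
                   f"(pf a1={pf.a1:.3f} b1={pf.b1:.3f} b2={pf.b2:.4f}; "
                   f"pob {pob.intercept:.3f}+{pob.slope:.4f}t)")
        for session in sessions:
            if (samples.subject, session) in aifs:
                continue
            target_meta = meta_by_key.get((samples.subject, session))
            if target_meta is None:
                continue
            aifs[(samples.subject, session)] = normalize_aif_to_session(
                aif, meta_by_key[key], target_meta,
                convention=config.suv_convention)

    mean_aif = None
    if len(measured) >= 2:
        mean_aif = build_mean_aif(measured, measured_metas)
        log.append(f"mean AIF built from {len(measured)} measured AIFs")

    # --- per-region fits ----------------------------------------------------
    rows: List[dict] = []
    for subject in subjects:
        for session in sessions:
            meta = meta_by_key.get((subject, session))
            aif = aifs.get((subject, session))
            ref_tac = _reference_tac(tacs_by_key, subject, session,
                                     config.reference_region)
            k2p: Optional[float]
            if isinstance(config.lr_k2_prime, (int, float)):
                k2p = float(config.lr_k2_prime)
            elif config.lr_k2_prime == "srtm-median":
                k2p = _session_k2_prime(tacs_by_key, subject, session,
                                        config.reference_region)
            else:
                k2p = None
            mean_aif_session = None
            if wants_mean and mean_aif is not None and meta is not None:
                mean_aif_session = normalize_aif_to_session(
                    mean_aif, mean_aif.meta, meta,
                    convention=config.suv_convention)

            region_keys = sorted({(t.region, t.side) for t in tacs
                                  if t.subject == subject and t.session == session})
            for region, side in region_keys:
                tac = tacs_by_key[(subject, session, region, side)]
                for model in config.models:
                    try:
                        new_rows = _run_model(
                            model, tac, aif, mean_aif_session, ref_tac, meta,
                            config, k2p)
                    except ValidationError as exc:
                        new_rows = [{"subject": subject, "session": session,
                                     "region": region, "side": side,
                                     "model": model, "metric": _main_metric(model),
                                     "value": np.nan, "failed": True,
                                     "failure_reason": str(exc)}]
                    for r in new_rows:
                        log.append(
                            f"{subject}/{session}/{region}/{side}/{model}: "
                            + ("failed: " + str(r.get("failure_reason", ""))
                               if r.get("failed") else "ok"))
                    rows.extend(new_rows)

    results = pd.DataFrame(rows)
    group_summary = aggregate_regions(
        results.dropna(subset=["metric"]), pairing=config.aggregation,
        exclusions=config.exclusions)
    comparison_frames = []
    for earlier, later in zip(sessions[:-1], sessions[1:]):
        comparison_frames.append(compare_sessions(
            results, earlier, later, alpha=config.alpha,
            exclusions=config.exclusions))
    comparisons = (pd.concat(comparison_frames, ignore_index=True)
                   if comparison_frames else pd.DataFrame())
    report = PipelineReport(results=results, group_summary=group_summary,
                            comparisons=comparisons, aifs=aifs,
                            mean_aif=mean_aif, log=log)
    _write_report(report, config)
    return report


def _main_metric(model: str) -> str:
    if model in AIF_MODELS or model == "1TC-mAIF":
        return "V_T"
    if model in ("LR", "SRTM"):
        return "DVR"
    return "SUV"


def _run_model(model, tac, aif, mean_aif_session, ref_tac, meta, config, k2p):
    if model in AIF_MODELS and aif is None:
        return []  # subject without arterial sampling: AIF arms are skipped
    if model == "LP":
        res = LoganPlot(tac, aif, t_star=config.logan_t_star_min).fit()
        return _metric_rows(res, model)
    if model == "1TC":
        res = OneTissueModel(tac, aif).fit()
        return _metric_rows(res, model)
    if model == "2TC":
        res = TwoTissueModel(tac, aif).fit()
        return _metric_rows(res, model)
    if model == "1TC-mAIF":
        if mean_aif_session is None:
            return []
        res = OneTissueModel(tac, mean_aif_session).fit()
        rows = _metric_rows(res, model)
        for r in rows:
            r["model"] = "1TC-mAIF"
        return rows
    if model in ("LR", "SRTM"):
        if ref_tac is None:
            raise ValidationError(
                f"reference region {config.reference_region!r} not in the TAC table")
        if tac.region == ref_tac.region:
            return []  # the reference is not quantified against itself
        if model == "LR":
            res = LoganReference(tac, ref_tac, k2_prime=k2p,
                                 t_star=config.logan_t_star_min).fit()
        else:
            res = SRTM(tac, ref_tac).fit()
        return _metric_rows(res, model)
    if model == "SUV":
        if meta is None:
            raise ValidationError("SUV requires session metadata")
        value = suv_summary(tac, meta, window=config.suv_window_min,
                            convention=config.suv_convention)
        return [{"subject": tac.subject, "session": tac.session,
                 "region": tac.region, "side": tac.side, "model": "SUV",
                 "metric": "SUV", "value": value, "failed": False,
                 "failure_reason": ""}]
    raise ConfigError(f"unknown model {model!r}")


def _config_hash(config: StudyConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.md5(payload.encode()).hexdigest()


def _write_report(report: PipelineReport, config: StudyConfig) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    report.results.to_csv(os.path.join(out, "results.csv"), index=False)
    report.group_summary.to_csv(os.path.join(out, "group_summary.csv"), index=False)
    report.comparisons.to_csv(os.path.join(out, "comparisons.csv"), index=False)
    with open(os.path.join(out, "run_log.txt"), "w") as fh:
        fh.write("\n".join(report.log) + "\n")
    with open(os.path.join(out, "summary.md"), "w") as fh:
        fh.write(summary_markdown(report))


def summary_markdown(report: PipelineReport) -> str:
    """Per-region longitudinal summary: mean +/- sd per session, percent
    change and bilateral significance markers for each model/metric."""
    lines = ["# Group summary", ""]
    if report.comparisons.empty:
        return "\n".join(lines + ["(no session comparisons available)"])
    gs = report.group_summary
    for (model, metric), comp in report.comparisons.groupby(["model", "metric"]):
        lines.append(f"## {model} — {metric}")
        lines.append("")
        lines.append("| region | " + " | ".join(
            f"{s} (mean ± sd)" for s in sorted(gs[gs['model'] == model]['session'].unique())
        ) + " | change | sig |")
        lines.append("|" + "---|" * (2 + gs[gs['model'] == model]['session'].nunique()))
        sub_gs = gs[(gs["model"] == model) & (gs["metric"] == metric)]
        for region, rcomp in comp.groupby("region"):
            cells = [region]
            for session in sorted(sub_gs["session"].unique()):
                row = sub_gs[(sub_gs["region"] == region)
                             & (sub_gs["session"] == session)]
                cells.append(f"{row['mean'].iloc[0]:.3g} ± {row['sd'].iloc[0]:.2g}"
                             if len(row) else "—")
            changes, sigs = [], []
            for _, cr in rcomp.iterrows():
                pct = cr["percent_change"]
                changes.append(f"{pct:+.0f}%" if np.isfinite(pct) else "—")
                sigs.append("**" if cr["bilateral_t"] else "")
            cells.append(", ".join(changes))
            cells.append(", ".join(sigs) if any(sigs) else "ns")
            lines.append("| " + " | ".join(cells) + " |")
        lines.append("")
    return "\n".join(lines)
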