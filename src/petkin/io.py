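"""CSV/JSON readers and writers for the study's tabular interchange formats.

Dialects (UTF-8, decimal point, comma or tab separated):

* TAC table: subject, session, region, side, frame_start_s, frame_end_s,
  kBq_per_mL (long format, one row per frame);
* blood table: subject, session, time_min, blood_kBq_per_mL,
  parent_fraction (empty where unmeasured; optional plasma_kBq_per_mL);
* sessions table: subject, session, dose_MBq, weight_g;
* input functions: two-column (time_min, kBq_per_mL) CSV plus a JSON
  sidecar with provenance, SUV convention and the parent-fraction begin.
"""

from __future__ import annotations

import json
import os
from typing import List, Optional

import numpy as np
import pandas as pd

from .curves import InputFunction, SessionMeta, TimeActivityCurve
from .exceptions import SchemaError, ValidationError
from .schedules import FrameSchedule

__all__ = [
    "read_tac_table", "read_blood_table", "read_sessions_table", "read_tables",
    "write_cohort_bundle", "write_input_function", "read_input_function",
]

TAC_COLUMNS = ["subject", "session", "region", "side",
               "frame_start_s", "frame_end_s", "kBq_per_mL"]
BLOOD_COLUMNS = ["subject", "session", "time_min", "blood_kBq_per_mL",
                 "parent_fraction"]
SESSION_COLUMNS = ["subject", "session", "dose_MBq", "weight_g"]


def _read_csv(path: str) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _require_columns(df: pd.DataFrame, required: List[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_tac_table(path: str) -> List[TimeActivityCurve]:
    """Read and validate a long-format TAC table into TimeActivityCurve objects."""
    df = _read_csv(path)
    _require_columns(df, TAC_COLUMNS, "TAC table")
    tacs = []
    for (subject, session, region, side), sub in df.groupby(
            ["subject", "session", "region", "side"], sort=True):
        sub = sub.sort_values("frame_start_s")
        start = sub["frame_start_s"].to_numpy(dtype=float)
        end = sub["frame_end_s"].to_numpy(dtype=float)
        try:
            schedule = FrameSchedule(start_s=start, end_s=end)
        except ValidationError as exc:
            raise ValidationError(
                f"invalid frame schedule for {subject}/{session} "
                f"{region} ({side}): {exc}") from exc
        tacs.append(TimeActivityCurve(
            subject=str(subject), session=str(session), region=str(region),
            side=str(side), schedule=schedule,
            values=sub["kBq_per_mL"].to_numpy(dtype=float), noise_flag=True))
    return tacs


def read_blood_table(path: str):
    """Read and validate a blood-sample table into BloodSampleSeries objects."""
    from .input_function import BloodSampleSeries

    df = _read_csv(path)
    _require_columns(df, BLOOD_COLUMNS, "blood table")
    out = []
    for (subject, session), sub in df.groupby(["subject", "session"], sort=True):
        sub = sub.sort_values("time_min")
        plasma = (sub["plasma_kBq_per_mL"].to_numpy(dtype=float)
                  if "plasma_kBq_per_mL" in sub.columns else None)
        try:
            out.append(BloodSampleSeries(
                subject=str(subject), session=str(session),
                time_min=sub["time_min"].to_numpy(dtype=float),
                blood_kBq_per_mL=sub["blood_kBq_per_mL"].to_numpy(dtype=float),
                parent_fraction=sub["parent_fraction"].to_numpy(dtype=float),
                plasma_kBq_per_mL=plasma))
        except ValidationError as exc:
            raise ValidationError(f"blood table {subject}/{session}: {exc}") from exc
    return out


def read_sessions_table(path: str) -> List[SessionMeta]:
    df = _read_csv(path)
    _require_columns(df, SESSION_COLUMNS, "sessions table")
    metas = []
    for i, row in df.iterrows():
        try:
            metas.append(SessionMeta(subject=str(row["subject"]),
                                     session=str(row["session"]),
                                     dose_MBq=float(row["dose_MBq"]),
                                     weight_g=float(row["weight_g"])))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"sessions table row {i}: {exc}") from exc
    return metas


def read_tables(tac_path: str, blood_path: Optional[str],
                sessions_path: str):
    """Read the three study tables; the blood table may be absent."""
    tacs = read_tac_table(tac_path)
    blood = read_blood_table(blood_path) if blood_path else []
    metas = read_sessions_table(sessions_path)
    return tacs, blood, metas


def write_cohort_bundle(bundle, out_dir: str, overwrite: bool = False) -> None:
    """Write tacs.csv, blood.csv, sessions.csv, truth.json and manifest.json."""
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not overwrite:
        raise ValidationError(
            f"output directory {out_dir!r} is not empty (pass overwrite=True)")
    os.makedirs(out_dir, exist_ok=True)
    bundle.tacs.to_csv(os.path.join(out_dir, "tacs.csv"), index=False)
    bundle.blood.to_csv(os.path.join(out_dir, "blood.csv"), index=False)
    bundle.sessions.to_csv(os.path.join(out_dir, "sessions.csv"), index=False)
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(bundle.manifest, fh, indent=1, sort_keys=True)


def write_input_function(aif: InputFunction, path: str,
                         convention: str = "as-printed",
                         begin_min: Optional[float] = None) -> None:
    """Two-column CSV plus a JSON sidecar (same path with .json appended)."""
    pd.DataFrame({"time_min": aif.t_min, "kBq_per_mL": aif.plasma}).to_csv(
        path, index=False)
    sidecar = {"provenance": aif.provenance, "suv_convention": convention,
               "begin_min": begin_min}
    if aif.meta is not None:
        sidecar.update(subject=aif.meta.subject, session=aif.meta.session,
                       dose_MBq=aif.meta.dose_MBq, weight_g=aif.meta.weight_g)
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_input_function(path: str) -> InputFunction:
    df = _read_csv(path)
    _require_columns(df, ["time_min", "kBq_per_mL"], "input-function file")
    meta = None
    provenance = "measured"
    sidecar_path = path + ".json"
    if os.path.exists(sidecar_path):
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        provenance = sidecar.get("provenance", "measured")
        if "dose_MBq" in sidecar:
            meta = SessionMeta(subject=sidecar["subject"],
                               session=sidecar["session"],
                               dose_MBq=sidecar["dose_MBq"],
                               weight_g=sidecar["weight_g"])
    return InputFunction(t_min=df["time_min"].to_numpy(dtype=float),
                         plasma=df["kBq_per_mL"].to_numpy(dtype=float),
                         provenance=provenance, meta=meta)
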