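"""Plain-text session serialization.

Layout of a session directory::

    trials.tsv            one row per trial
    eye/trial_<id>.csv    columns time_s, x_deg, y_deg
    spikes/cell_<id>.tsv  columns time_s, type (SS|CS)
    session.yaml          kinematics config, seed, region + ground truth per cell

All times are seconds from session start.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .synthgen import CellConfig, ConditionKinematics, KinematicsConfig
from .types import CellRecording, EyeTrace, SaccadeEvent, Session, TrialRecord

_SACC_FIELDS = ["onset", "offset", "amplitude", "peak_velocity", "duration",
                "direction", "reaction_time", "x_start", "y_start", "x_end", "y_end"]


def _saccade_cols(prefix: str, sacc: Optional[SaccadeEvent]) -> dict:
    if sacc is None:
        return {f"{prefix}_{f}": np.nan for f in _SACC_FIELDS}
    return {f"{prefix}_{f}": getattr(sacc, f) for f in _SACC_FIELDS}


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        row = {"trial_id": t.trial_id, "condition": t.condition,
               "direction": t.direction, "target_amplitude": t.target_amplitude,
               "t_fix_on": t.t_fix_on, "t_target_on": t.t_target_on,
               "t_go": t.t_go, "instruction_duration": t.instruction_duration,
               "t_end": t.t_end, "outcome": t.outcome,
               "exclusion_reason": t.exclusion_reason}
        row.update(_saccade_cols("gt", t.ground_truth_saccade))
        row.update(_saccade_cols("det", t.saccade))
        rows.append(row)
    return pd.DataFrame(rows)


def _saccade_from_row(row, prefix: str) -> Optional[SaccadeEvent]:
    onset = row.get(f"{prefix}_onset", np.nan)
    if onset is None or (isinstance(onset, float) and np.isnan(onset)):
        return None
    kw = {f: row[f"{prefix}_{f}"] for f in _SACC_FIELDS}
    if isinstance(kw["reaction_time"], float) and np.isnan(kw["reaction_time"]):
        kw["reaction_time"] = None
    return SaccadeEvent(**kw)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    trials = []
    for _, row in df.iterrows():
        trials.append(TrialRecord(
            trial_id=int(row.trial_id), condition=row.condition,
            direction=int(row.direction), target_amplitude=float(row.target_amplitude),
            t_fix_on=float(row.t_fix_on), t_target_on=float(row.t_target_on),
            t_go=float(row.t_go), instruction_duration=float(row.instruction_duration),
            t_end=float(row.t_end), outcome=row.outcome,
            exclusion_reason="" if pd.isna(row.exclusion_reason) else str(row.exclusion_reason),
            ground_truth_saccade=_saccade_from_row(row, "gt"),
            saccade=_saccade_from_row(row, "det")))
    return trials


def save_session(session: Session, path: str | Path) -> Path:
    path = Path(path)
    (path / "eye").mkdir(parents=True, exist_ok=True)
    (path / "spikes").mkdir(parents=True, exist_ok=True)
    trials_to_frame(session.trials).to_csv(path / "trials.tsv", sep="\t", index=False)
    for tid, trace in session.eye.items():
        pd.DataFrame({"time_s": trace.time, "x_deg": trace.x, "y_deg": trace.y}) \
            .to_csv(path / "eye" / f"trial_{tid}.csv", index=False)
    meta_cells = []
    for cell in session.cells:
        df = pd.DataFrame({
            "time_s": np.concatenate([cell.ss_times, cell.cs_times]),
            "type": ["SS"] * cell.ss_times.size + ["CS"] * cell.cs_times.size})
        df = df.sort_values(["time_s", "type"], kind="stable")
        df.to_csv(path / "spikes" / f"cell_{cell.cell_id}.tsv", sep="\t", index=False)
        meta_cells.append({
            "cell_id": cell.cell_id, "region": cell.region,
            "ground_truth": dataclasses.asdict(cell.ground_truth)
            if isinstance(cell.ground_truth, CellConfig) else None})
    meta = {"seed": session.seed, "cells": meta_cells,
            "kinematics": dataclasses.asdict(session.kinematics)
            if isinstance(session.kinematics, KinematicsConfig) else None}
    with open(path / "session.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def _kin_from_dict(d: Optional[dict]) -> Optional[KinematicsConfig]:
    if d is None:
        return None
    d = dict(d)
    for cond in ("pro", "anti"):
        d[cond] = ConditionKinematics(**d[cond])
    return KinematicsConfig(**d)


def load_session(path: str | Path) -> Session:
    path = Path(path)
    trials = frame_to_trials(pd.read_csv(path / "trials.tsv", sep="\t"))
    with open(path / "session.yaml") as fh:
        meta = yaml.safe_load(fh)
    kin = _kin_from_dict(meta.get("kinematics"))
    fs = kin.sampling_rate if kin is not None else 350.0
    eye = {}
    for t in trials:
        f = path / "eye" / f"trial_{t.trial_id}.csv"
        if f.exists():
            df = pd.read_csv(f)
            eye[t.trial_id] = EyeTrace(time=df.time_s.to_numpy(),
                                       x=df.x_deg.to_numpy(), y=df.y_deg.to_numpy(),
                                       sampling_rate=fs)
    cells = []
    for mc in meta.get("cells", []):
        df = pd.read_csv(path / "spikes" / f"cell_{mc['cell_id']}.tsv", sep="\t")
        gt = CellConfig(**mc["ground_truth"]) if mc.get("ground_truth") else None
        cells.append(CellRecording(
            cell_id=str(mc["cell_id"]), region=mc["region"],
            ss_times=df.loc[df.type == "SS", "time_s"].to_numpy(),
            cs_times=df.loc[df.type == "CS", "time_s"].to_numpy(),
            trials=trials, ground_truth=gt))
    return Session(trials=trials, eye=eye, cells=cells,
                   seed=meta.get("seed"), kinematics=kin)
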