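"""Session-log, trace, fit-result, and regressor file formats.

Everything is plain text: session logs are CSV (one row per trial), traces
and regressor tables are TSV, fit results and BMS reports are JSON, run
configurations are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .inference import FitResult
from .models.mixture import ControllerTrace, classify_trial
from .selection import BMSResult
from .task import (
    BlockSchedule,
    InvalidConfigError,
    Mode,
    ScheduleEntry,
    SessionData,
    TrialRecord,
    build_schedule,
)

__all__ = [
    "SESSION_COLUMNS",
    "session_to_frame",
    "write_session",
    "read_sessions",
    "write_fit_result",
    "read_evidence_dir",
    "write_bms_result",
    "export_regressors",
    "load_schedule_config",
]

SESSION_COLUMNS = [
    "subject_id",
    "trial",
    "mode",
    "participant_choice",
    "aa_choice",
    "outcome",
    "participant_stay",
    "aa_stay",
]

ONSETS = ("cue", "press", "aa_choice", "feedback")


def session_to_frame(session: SessionData) -> pd.DataFrame:
    rows = []
    for r in session.records:
        rows.append(
            {
                "subject_id": session.subject_id,
                "trial": r.trial,
                "mode": r.mode.value,
                "participant_choice": r.participant_choice,
                "aa_choice": r.aa_choice,
                "outcome": r.outcome,
                "participant_stay": "" if r.participant_stay is None else r.participant_stay,
                "aa_stay": "" if r.aa_stay is None else r.aa_stay,
            }
        )
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_session(session: SessionData, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    session_to_frame(session).to_csv(path, index=False)
    return path


class SessionFormatError(ValueError):
    pass


def _frame_to_sessions(df: pd.DataFrame, source: str) -> list[SessionData]:
    missing = [c for c in SESSION_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{source}: missing columns {missing}")
    sessions = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("trial")
        records = []
        prev_pc = prev_aa = None
        entries = []
        for _, row in grp.iterrows():
            t = int(row["trial"])
            pc, aa, out = (
                int(row["participant_choice"]),
                int(row["aa_choice"]),
                int(row["outcome"]),
            )
            if pc not in (0, 1) or aa not in (0, 1):
                raise SessionFormatError(
                    f"{source}: subject {sid} trial {t}: non-binary choice"
                )
            if out != int(pc == aa):
                raise SessionFormatError(
                    f"{source}: subject {sid} trial {t}: outcome inconsistent "
                    "with choices"
                )
            mode = Mode(str(row["mode"]))
            records.append(
                TrialRecord(
                    trial=t,
                    mode=mode,
                    participant_choice=pc,
                    aa_choice=aa,
                    outcome=out,
                    participant_stay=None if prev_pc is None else int(prev_pc == pc),
                    aa_stay=None if prev_aa is None else int(prev_aa == aa),
                )
            )
            entries.append(ScheduleEntry(t, mode, 0))
            prev_pc, prev_aa = pc, aa
        schedule = _infer_schedule(entries)
        sessions.append(
            SessionData(
                subject_id=str(sid), records=tuple(records), schedule=schedule
            )
        )
    return sessions


def _infer_schedule(entries: list[ScheduleEntry]) -> BlockSchedule:
    out = []
    block_id = 0
    prev_mode = None
    for e in entries:
        if e.mode is not prev_mode:
            if not (prev_mode is None and e.mode is Mode.INIT):
                block_id += 1 if prev_mode is not None or e.mode is not Mode.INIT else 0
            prev_mode = e.mode
        out.append(ScheduleEntry(e.trial, e.mode, block_id if e.mode is not Mode.INIT else 0))
    return BlockSchedule(tuple(out))


def read_sessions(path: str | Path) -> list[SessionData]:
    """Read session logs from one CSV file or a directory of CSV files."""
    path = Path(path)
    if path.is_dir():
        sessions = []
        for f in sorted(path.glob("*.csv")):
            sessions.extend(_frame_to_sessions(pd.read_csv(f), str(f)))
        return sessions
    return _frame_to_sessions(pd.read_csv(path), str(path))


def write_fit_result(fit: FitResult, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(fit.to_dict(), indent=2))
    return path


def read_evidence_dir(directory: str | Path):
    """Collect per-subject x model free energies from a directory of fit JSONs.

    Returns (F matrix, subject ids, model names).
    """
    directory = Path(directory)
    table: dict[str, dict[str, float]] = {}
    for f in sorted(directory.glob("*.json")):
        d = json.loads(f.read_text())
        if not {"subject_id", "model", "free_energy"} <= set(d):
            continue  # manifest or unrelated JSON
        table.setdefault(d["subject_id"], {})[d["model"]] = d["free_energy"]
    if not table:
        raise FileNotFoundError(f"no fit-result JSONs under {directory}")
    subjects = sorted(table)
    models = sorted({m for row in table.values() for m in row})
    F = np.empty((len(subjects), len(models)))
    for i, s in enumerate(subjects):
        for j, m in enumerate(models):
            if m not in table[s]:
                raise ValueError(f"subject {s} lacks a fit for model {m}")
            F[i, j] = table[s][m]
    return F, subjects, models


def write_bms_result(result: BMSResult, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "models": list(result.model_names),
        "alpha": [float(x) for x in result.alpha],
        "expected_freq": [float(x) for x in result.expected_freq],
        "ep": [float(x) for x in result.ep],
        "bor": float(result.bor),
        "pep": [float(x) for x in result.pep],
        "winner": result.winner,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def export_regressors(
    session: SessionData,
    trace: ControllerTrace,
    delta_bias: float,
    path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Trial-level parametric regressor table (one row per trial x onset).

    Parametric columns (reliability difference, lagged cooperativity
    signature / win / switch, decision value of staying, prediction error,
    classification) are attached unorthogonalized to the cue and feedback
    onsets; press and AA-choice onsets carry empty parametric fields, as do
    trials with a missing response.
    """
    if len(trace) != len(session):
        raise ValueError("trace length must match the session")
    recs = session.records
    rows = []
    for t, r in enumerate(recs):
        missing = r.participant_choice not in (0, 1)
        coop_sig_tm1 = win_tm1 = switch_tm1 = ""
        if t >= 1 and not missing:
            prev = recs[t - 1]
            win_tm1 = prev.outcome
            switch_tm1 = "" if r.participant_stay is None else 1 - r.participant_stay
            if r.aa_stay is not None:
                coop_sig_tm1 = int(
                    (prev.outcome == 1 and r.aa_stay == 1)
                    or (prev.outcome == 0 and r.aa_stay == 0)
                )
        for onset in ONSETS:
            parametric = (not missing) and onset in ("cue", "feedback")
            rows.append(
                {
                    "trial": r.trial,
                    "mode": r.mode.value,
                    "onset": onset,
                    "Delta": trace.delta[t] if parametric else "",
                    "coop_sig_tm1": coop_sig_tm1 if parametric else "",
                    "win_tm1": win_tm1 if parametric else "",
                    "switch_tm1": switch_tm1 if parametric else "",
                    "DV_stay": (
                        trace.dv_stay[t]
                        if parametric and np.isfinite(trace.dv_stay[t])
                        else ""
                    ),
                    "rPE": trace.rpe[t] if parametric and onset == "feedback" else "",
                    "classification": (
                        classify_trial(trace.delta[t], delta_bias)
                        if parametric
                        else ""
                    ),
                }
            )
    df = pd.DataFrame(rows)
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=False)
    return df


def load_schedule_config(path: str | Path) -> BlockSchedule:
    """Schedule from a YAML/JSON config with n_trials/init_len/comp_len/coop_len/start_mode."""
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise InvalidConfigError(f"{path}: expected a mapping")
    return build_schedule(
        n_trials=int(cfg.get("n_trials", 163)),
        init_len=int(cfg.get("init_len", 5)),
        comp_len=int(cfg.get("comp_len", 13)),
        coop_len=int(cfg.get("coop_len", 10)),
        start_mode=Mode(cfg.get("start_mode", "COMPETITIVE")),
    )
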