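"""Readers and writers for the session CSV dialects.

All files are plain CSV with validated headers; landmark columns use the
1-based 68-point naming (``x1,y1,…,x68,y68``).  See docs/FORMATS.md for the
column-by-column description.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .session import (
    AnswerRecord,
    CHOICES,
    Comparison,
    ComparisonSchedule,
    EMOTION_COLUMNS,
    QuestionnaireResponse,
)

__all__ = [
    "read_frames",
    "write_frames",
    "read_landmarks",
    "write_landmarks",
    "read_gaze",
    "write_gaze",
    "read_schedule",
    "write_schedule",
    "read_answers",
    "write_answers",
    "read_questionnaire",
    "write_questionnaire",
    "write_session_dir",
]

logger = logging.getLogger("jurysense.io")

FRAME_REQUIRED = ("timestamp_s", *EMOTION_COLUMNS, "attention")
LANDMARK_COLUMNS = ("timestamp_s",) + tuple(
    f"{axis}{i}" for i in range(1, 69) for axis in ("x", "y")
)
GAZE_COLUMNS = ("timestamp_s", "gaze_x_cm", "gaze_y_cm", "available")
SCHEDULE_COLUMNS = (
    "comparison_index", "sound_first", "sound_second",
    "t_start_first", "t_end_first", "t_start_second", "t_end_second",
)
ANSWER_COLUMNS = ("comparison_index", "q1_choice", "q2_choice")
QUESTIONNAIRE_COLUMNS = ("juror_id", "period", "state")


def _check_header(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_frames(path) -> pd.DataFrame:
    """Frame CSV: timestamp, emotion percentages, optional neutral, attention.

    The attention column accepts true/false strings, 0/1 or blanks (missing);
    rows stay in file order.  Emotion values may be raw scores rather than
    percentages; normalisation is the caller's choice.
    """
    df = pd.read_csv(path)
    _check_header(df, FRAME_REQUIRED, path)
    attn = df["attention"]
    if attn.dtype == object:
        attn = attn.astype(str).str.strip().str.lower().map(
            {"true": 1.0, "false": 0.0, "1": 1.0, "0": 0.0,
             "1.0": 1.0, "0.0": 0.0, "": np.nan, "nan": np.nan}
        )
    df["attention"] = pd.to_numeric(attn, errors="coerce")
    n_bad = int(df["attention"].isna().sum())
    if n_bad:
        logger.warning("%s: %d rows with missing/unparseable attention", path, n_bad)
    return df


def write_frames(frames: pd.DataFrame, path) -> None:
    cols = [c for c in frames.columns if c not in ("valence", "engagement")]
    out = frames[cols].copy()
    out["attention"] = frames["attention"].astype(bool)
    out.to_csv(path, index=False)


def read_landmarks(path) -> tuple[np.ndarray, np.ndarray]:
    """Landmark CSV -> (timestamps (n,), points (n, 68, 2))."""
    df = pd.read_csv(path)
    _check_header(df, LANDMARK_COLUMNS, path)
    t = df["timestamp_s"].to_numpy(dtype=float)
    pts = df[list(LANDMARK_COLUMNS[1:])].to_numpy(dtype=float).reshape(-1, 68, 2)
    return t, pts


def write_landmarks(timestamps: np.ndarray, points: np.ndarray, path) -> None:
    flat = np.asarray(points, dtype=float).reshape(len(timestamps), 136)
    df = pd.DataFrame(flat, columns=list(LANDMARK_COLUMNS[1:]))
    df.insert(0, "timestamp_s", timestamps)
    df.to_csv(path, index=False, float_format="%.3f")


def read_gaze(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_header(df, GAZE_COLUMNS, path)
    df["available"] = df["available"].astype(bool)
    return df


def write_gaze(gaze: pd.DataFrame, path) -> None:
    gaze.to_csv(path, index=False, float_format="%.3f")


def read_schedule(path) -> ComparisonSchedule:
    df = pd.read_csv(path)
    _check_header(df, SCHEDULE_COLUMNS, path)
    comparisons = tuple(
        Comparison(
            index=int(r.comparison_index),
            sound_first=str(r.sound_first),
            sound_second=str(r.sound_second),
            t_start_first=float(r.t_start_first),
            t_end_first=float(r.t_end_first),
            t_start_second=float(r.t_start_second),
            t_end_second=float(r.t_end_second),
        )
        for r in df.itertuples()
    )
    sounds = tuple(dict.fromkeys(
        s for c in comparisons for s in (c.sound_first, c.sound_second)
    ))
    return ComparisonSchedule(sounds=sounds, comparisons=comparisons)


def write_schedule(schedule: ComparisonSchedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_answers(path) -> list[AnswerRecord]:
    df = pd.read_csv(path)
    _check_header(df, ANSWER_COLUMNS, path)
    answers = []
    for r in df.itertuples():
        q1 = str(r.q1_choice).strip().lower()
        q2 = str(r.q2_choice).strip().lower()
        if q1 not in CHOICES or q2 not in CHOICES:
            logger.warning("%s: row %d has invalid choice, skipped", path, r.Index)
            continue
        answers.append(AnswerRecord(int(r.comparison_index), q1, q2))
    return answers


def write_answers(answers: list[AnswerRecord], path) -> None:
    pd.DataFrame(
        [
            {"comparison_index": a.comparison_index,
             "q1_choice": a.q1_choice, "q2_choice": a.q2_choice}
            for a in answers
        ]
    ).to_csv(path, index=False)


def read_questionnaire(path) -> dict[str, tuple[QuestionnaireResponse, ...]]:
    """Questionnaire CSV -> mapping juror_id -> responses."""
    df = pd.read_csv(path)
    _check_header(df, QUESTIONNAIRE_COLUMNS, path)
    out: dict[str, list[QuestionnaireResponse]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.juror_id), []).append(
            QuestionnaireResponse(str(r.period), str(r.state))
        )
    return {k: tuple(v) for k, v in out.items()}


def write_questionnaire(responses_by_juror: dict, path) -> None:
    rows = [
        {"juror_id": juror, "period": r.period, "state": r.state}
        for juror, responses in responses_by_juror.items()
        for r in responses
    ]
    pd.DataFrame(rows, columns=list(QUESTIONNAIRE_COLUMNS)).to_csv(path, index=False)


def write_session_dir(session, out_dir) -> Path:
    """Write all files of one synthetic session into ``out_dir/<juror_id>``."""
    d = Path(out_dir) / session.juror_id
    d.mkdir(parents=True, exist_ok=True)
    write_frames(session.frames, d / "frames.csv")
    write_landmarks(
        session.frames["timestamp_s"].to_numpy(), session.landmarks, d / "landmarks.csv"
    )
    write_gaze(session.gaze, d / "gaze.csv")
    write_schedule(session.schedule, d / "schedule.csv")
    write_answers(session.answers, d / "answers.csv")
    write_questionnaire({session.juror_id: session.responses}, d / "questionnaire.csv")
    with open(d / "manifest.json", "w") as fh:
        json.dump(session.manifest, fh, indent=2, sort_keys=True)
    return d
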