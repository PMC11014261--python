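"""End-to-end analysis runner: clean → metrics → segment → trends → reports.

Operates on session directories as written by :func:`jurysense.io.write_session_dir`
(or any data in the same CSV dialects) and on in-memory
:class:`~jurysense.synthetic.SyntheticSession` objects, so the CLI and the
test suite share one code path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as jio
from .config import PipelineConfig
from .inference import JurorReliability, correlation_threshold_curve, juror_reliability
from .questionnaire import (
    AttentionSession,
    baseline_deltas,
    median_attention_by_state,
    reduction_fractions,
)
from .session import attach_metrics, clean_frames, segment_frames

__all__ = ["SessionAnalysis", "analyze_session", "analyze_cohort", "write_reports"]

logger = logging.getLogger("jurysense.pipeline")


@dataclass
class SessionAnalysis:
    juror_id: str
    reliability: JurorReliability
    segments: list
    attention_record: AttentionSession
    n_frames_read: int
    n_frames_clean: int


def _analyze(
    juror_id: str,
    frames: pd.DataFrame,
    schedule,
    answers,
    responses,
    cfg: PipelineConfig,
) -> SessionAnalysis:
    n_read = len(frames)
    frames = clean_frames(frames, window=(0.0, schedule.t_end))
    frames = attach_metrics(frames)
    segments = segment_frames(frames, schedule, answers)
    n_usable = sum(s.usable for s in segments)
    logger.info(
        "%s: %d frames read, %d after cleaning, %d/%d usable segments, "
        "attentive fraction %.3f",
        juror_id, n_read, len(frames), n_usable, len(segments),
        float(frames["attention"].mean()) if len(frames) else float("nan"),
    )
    rel = juror_reliability(
        juror_id,
        segments,
        min_frames=cfg.min_frames,
        slope_tie_epsilon=cfg.slope_tie_epsilon,
        trend_encoding=cfg.trend_encoding,
    )
    record = AttentionSession(
        juror_id=juror_id,
        timestamps=frames["timestamp_s"].to_numpy(),
        attention=frames["attention"].to_numpy(dtype=float),
        responses=tuple(responses),
    )
    return SessionAnalysis(
        juror_id=juror_id,
        reliability=rel,
        segments=segments,
        attention_record=record,
        n_frames_read=n_read,
        n_frames_clean=len(frames),
    )


def analyze_session(source, cfg: PipelineConfig | None = None) -> SessionAnalysis:
    """Analyze one juror session from a directory or a SyntheticSession."""
    cfg = cfg or PipelineConfig()
    if isinstance(source, (str, Path)):
        d = Path(source)
        frames = jio.read_frames(d / "frames.csv")
        schedule = jio.read_schedule(d / "schedule.csv")
        answers = jio.read_answers(d / "answers.csv")
        responses_by_juror = jio.read_questionnaire(d / "questionnaire.csv")
        juror_id = d.name
        responses = responses_by_juror.get(juror_id, ())
    else:
        frames = source.frames
        schedule = source.schedule
        answers = source.answers
        responses = source.responses
        juror_id = source.juror_id
    return _analyze(juror_id, frames, schedule, answers, responses, cfg)


def analyze_cohort(
    sources, cfg: PipelineConfig | None = None
) -> tuple[list[SessionAnalysis], pd.DataFrame, dict]:
    """Analyze every session and assemble the cohort-level reports.

    Returns the per-session analyses, the reliability table
    (juror_id, question, variant, rho, n) and a summary dict holding the
    juror-count-vs-ρ-threshold curve, the per-(state, period) median
    attention cells and the baseline-delta reduction fractions.
    """
    cfg = cfg or PipelineConfig()
    analyses = [analyze_session(s, cfg) for s in sources]

    rows = []
    for a in analyses:
        r = a.reliability
        for question in ("q1", "q2"):
            for variant, rho, n in (
                ("all", getattr(r, f"rho_{question}_all"), r.n_comparisons_all),
                ("filtered", getattr(r, f"rho_{question}_filtered"),
                 r.n_comparisons_filtered),
            ):
                rows.append(
                    {"juror_id": r.juror_id, "question": question,
                     "variant": variant, "rho": rho, "n": n}
                )
    reliability = pd.DataFrame(rows)

    thresholds = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    curves = {
        q: correlation_threshold_curve(
            [a.reliability for a in analyses], thresholds, question=q
        ).to_dict(orient="list")
        for q in ("q1", "q2")
    }

    records = [a.attention_record for a in analyses]
    cells = median_attention_by_state(records, boundaries=cfg.period_boundaries)
    deltas = baseline_deltas(records, boundaries=cfg.period_boundaries)
    summary = {
        "threshold_curves": curves,
        "median_attention_by_state": [
            {"state": c.state, "period": c.period,
             "median_attention": c.median_attention, "n_jurors": c.n_jurors}
            for c in cells
        ],
        "reduction_fractions": reduction_fractions(deltas),
        "n_jurors": len(analyses),
    }
    return analyses, reliability, summary


def write_reports(
    analyses: list[SessionAnalysis],
    reliability: pd.DataFrame,
    summary: dict,
    out_dir,
    cfg: PipelineConfig | None = None,
) -> None:
    """Write the cohort CSV/JSON reports into ``out_dir``."""
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reliability.to_csv(out / "reliability.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    deltas = baseline_deltas(
        [a.attention_record for a in analyses], boundaries=cfg.period_boundaries
    )
    deltas.to_csv(out / "deltas.csv", index=False)
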