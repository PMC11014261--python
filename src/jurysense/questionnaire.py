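"""Tool-computed attention versus self-reported concentration states.

After the test every juror reports a concentration state (from 'fully
focused' down to 'mentally fatigued') for three periods: the beginning,
middle and end of the session.  The attention classifier's Boolean stream,
averaged within each period, gives a per-period attentive fraction per
juror.  Cohort statistics then relate the two:

* per (state, period) cell, the median attentive fraction across jurors who
  reported that state in that period;
* per juror, baseline deltas — each state's attention minus the attention
  of that juror's 'fully focused' period (so the baseline maps to 0 and a
  negative delta means the tool saw less attention when the juror felt
  e.g. distracted);
* per state, the fraction of contributing jurors whose delta is strictly
  negative (the reduction fraction).

Period boundaries default to equal thirds of the cleaned session span and
are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import PERIODS, STATES, QuestionnaireResponse

__all__ = [
    "AttentionSession",
    "StateAttentionSummary",
    "period_boundaries",
    "period_means",
    "median_attention_by_state",
    "baseline_deltas",
    "reduction_fractions",
]

BASELINE_STATE = "fully_focused"


@dataclass
class AttentionSession:
    """The minimal per-juror input: attention stream plus self reports."""

    juror_id: str
    timestamps: np.ndarray
    attention: np.ndarray  # Boolean / 0-1 per frame
    responses: tuple[QuestionnaireResponse, ...]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.attention = np.asarray(self.attention, dtype=float)
        if self.timestamps.shape != self.attention.shape:
            raise ValueError("timestamps and attention must have equal length")
        periods = [r.period for r in self.responses]
        if len(periods) != len(set(periods)):
            raise ValueError("at most one questionnaire state per period")

    def state_of(self, period: str) -> str | None:
        for r in self.responses:
            if r.period == period:
                return r.state
        return None


@dataclass(frozen=True)
class StateAttentionSummary:
    state: str
    period: str
    median_attention: float
    n_jurors: int


def period_boundaries(
    timestamps: np.ndarray, boundaries: tuple[float, float] | None = None
) -> tuple[float, float, float, float]:
    """Edges (e0, e1, e2, e3) of the three reporting periods.

    ``boundaries`` gives the two interior edges; by default the session span
    is split into equal thirds.
    """
    t = np.asarray(timestamps, dtype=float)
    if len(t) == 0:
        raise ValueError("empty attention session")
    e0, e3 = float(t.min()), float(t.max())
    if boundaries is None:
        span = e3 - e0
        return e0, e0 + span / 3.0, e0 + 2.0 * span / 3.0, e3
    b1, b2 = boundaries
    if not e0 <= b1 <= b2 <= e3:
        raise ValueError("period boundaries must be ordered within the session span")
    return e0, float(b1), float(b2), e3


def period_means(
    session: AttentionSession, boundaries: tuple[float, float] | None = None
) -> dict[str, float]:
    """Mean attentive fraction per reporting period for one juror.

    Periods are half-open except the last, which includes the final frame.
    Periods without frames are omitted.
    """
    edges = period_boundaries(session.timestamps, boundaries)
    out: dict[str, float] = {}
    for k, period in enumerate(PERIODS):
        lo, hi = edges[k], edges[k + 1]
        if k < len(PERIODS) - 1:
            mask = (session.timestamps >= lo) & (session.timestamps < hi)
        else:
            mask = (session.timestamps >= lo) & (session.timestamps <= hi)
        if mask.any():
            out[period] = float(session.attention[mask].mean())
    return out


def _state_attention_pairs(
    session: AttentionSession, boundaries: tuple[float, float] | None
) -> list[tuple[str, str, float]]:
    means = period_means(session, boundaries)
    return [
        (session.state_of(p), p, m)
        for p, m in means.items()
        if session.state_of(p) is not None
    ]


def median_attention_by_state(
    sessions: list[AttentionSession],
    boundaries: tuple[float, float] | None = None,
) -> list[StateAttentionSummary]:
    """Median attentive fraction per (state, period) cell across the cohort.

    Each juror contributes their period-mean attention to the cell of the
    state they reported for that period; cells with no contributing juror
    are omitted with a warning.
    """
    cells: dict[tuple[str, str], list[float]] = {}
    for s in sessions:
        for state, period, mean in _state_attention_pairs(s, boundaries):
            cells.setdefault((state, period), []).append(mean)
    summaries = []
    for state in STATES:
        for period in PERIODS:
            vals = cells.get((state, period))
            if not vals:
                continue
            summaries.append(
                StateAttentionSummary(
                    state=state,
                    period=period,
                    median_attention=float(np.median(vals)),
                    n_jurors=len(vals),
                )
            )
    if not summaries:
        warnings.warn("no (state, period) cell had contributing jurors", stacklevel=2)
    return summaries


def baseline_deltas(
    sessions: list[AttentionSession],
    boundaries: tuple[float, float] | None = None,
    baseline_state: str = BASELINE_STATE,
) -> pd.DataFrame:
    """Per-juror attention deltas against that juror's baseline-state period.

    A juror reporting the baseline state in several periods (or any state in
    several periods) contributes the mean of those period means.  Jurors who
    never reported the baseline state are excluded with a warning.  Columns:
    ``juror_id``, ``state``, ``delta``; the baseline state's own delta is
    exactly 0.
    """
    rows = []
    for s in sessions:
        per_state: dict[str, list[float]] = {}
        for state, _period, mean in _state_attention_pairs(s, boundaries):
            per_state.setdefault(state, []).append(mean)
        if baseline_state not in per_state:
            warnings.warn(
                f"juror {s.juror_id!r} never reported {baseline_state!r}; excluded",
                stacklevel=2,
            )
            continue
        base = float(np.mean(per_state[baseline_state]))
        for state, means in per_state.items():
            rows.append(
                {
                    "juror_id": s.juror_id,
                    "state": state,
                    "delta": 0.0 if state == baseline_state
                    else float(np.mean(means)) - base,
                }
            )
    return pd.DataFrame(rows, columns=["juror_id", "state", "delta"])


def reduction_fractions(deltas: pd.DataFrame) -> dict[str, float]:
    """Fraction of contributing jurors with a strictly negative delta, per
    non-baseline state present in ``deltas``."""
    out: dict[str, float] = {}
    if len(deltas) == 0:
        return out
    for state, group in deltas.groupby("state"):
        if state == BASELINE_STATE:
            continue
        out[str(state)] = float((group["delta"] < 0).mean())
    return out
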