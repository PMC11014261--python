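"""Segmentation-regression choice inference and attention-filtered reliability.

For every sound sub-segment an ordinary least-squares line is fitted to the
valence time series.  The relative trend of the two lines in a pairwise
comparison predicts the juror's answers: the sub-segment with the larger
slope is the predicted higher-quality choice (q2), the one with the smaller
slope the predicted more-annoying choice (q1) — a rising valence signals
approval, a falling one annoyance.  This is stated in the source criterion
for one rising and one falling trend and generalised here to ordering by
slope; a strict mode abstains unless the signs differ.

Juror reliability is the Spearman rank correlation between the juror's
actual answers (+1 = chose second, −1 = chose first) and the trend-derived
prediction for the same comparisons.  By default the prediction is encoded
as the sign of the slope difference (the simulated choice), so a juror who
always follows the criterion scores exactly +1; encoding the raw slope
difference instead is available via ``trend_encoding='difference'``.
Attention filtering refits every trend on attentive frames only and drops
comparisons left with too few attentive frames, quantifying how much
inattention noise degrades the answer–valence agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session import ComparisonSegment, InsufficientDataError

__all__ = [
    "TrendFit",
    "SimulatedChoice",
    "JurorReliability",
    "fit_segment_trend",
    "simulate_choices",
    "juror_answer_correlation",
    "juror_reliability",
    "correlation_threshold_curve",
]


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of valence against time for one sound sub-segment.

    ``rho`` is the Pearson correlation of valence with time; with the
    population (N-normalised) standard deviations the N vs N−1 factors
    cancel, so it equals the standard sample estimate.  For simple linear
    regression ``rho² == r_squared``.
    """

    slope: float
    intercept: float
    r_squared: float
    rho: float
    n_frames: int


@dataclass(frozen=True)
class SimulatedChoice:
    comparison_index: int
    predicted_q1: str  # 'first' | 'second' | 'abstain'
    predicted_q2: str
    slope_first: float
    slope_second: float


@dataclass(frozen=True)
class JurorReliability:
    """Answer–valence correlations for one juror, with and without the
    attention filter; NaN marks an insufficient-data variant."""

    juror_id: str
    rho_q1_all: float
    rho_q2_all: float
    rho_q1_filtered: float
    rho_q2_filtered: float
    n_comparisons_all: int
    n_comparisons_filtered: int


def fit_segment_trend(frames_or_t, valence=None) -> TrendFit:
    """OLS of valence on time for one sub-segment.

    Accepts either a frames DataFrame with ``timestamp_s``/``valence``
    columns or two arrays.  Constant valence returns the degenerate-fit
    convention (slope 0, R² 0, rho 0); fewer than two distinct timestamps
    raises :class:`InsufficientDataError`.
    """
    if valence is None:
        t = frames_or_t["timestamp_s"].to_numpy(dtype=float)
        v = frames_or_t["valence"].to_numpy(dtype=float)
    else:
        t = np.asarray(frames_or_t, dtype=float)
        v = np.asarray(valence, dtype=float)
    if len(t) < 2 or np.ptp(t) == 0:
        raise InsufficientDataError(
            f"need >= 2 frames with distinct timestamps, got {len(t)}"
        )
    if np.ptp(v) == 0:
        return TrendFit(0.0, float(v.mean()), 0.0, 0.0, len(t))
    res = stats.linregress(t, v)
    rho = float(res.rvalue)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=rho * rho,
        rho=rho,
        n_frames=len(t),
    )


def _segment_slopes(
    seg: ComparisonSegment,
    min_frames: int,
    attention_filter: bool,
) -> tuple[float, float] | None:
    """Fitted slopes of both sub-segments, or None when unusable."""
    slopes = []
    for frames in (seg.frames_first, seg.frames_second):
        if attention_filter and len(frames) > 0:
            frames = frames.loc[frames["attention"].astype(bool)]
        if len(frames) < max(min_frames, 2):
            return None
        try:
            slopes.append(fit_segment_trend(frames).slope)
        except InsufficientDataError:
            return None
    return slopes[0], slopes[1]


def simulate_choices(
    seg: ComparisonSegment,
    min_frames: int = 5,
    slope_tie_epsilon: float = 0.0,
    require_opposite_signs: bool = False,
    attention_filter: bool = False,
) -> SimulatedChoice:
    """Predict both answers of one comparison from the relative valence trend.

    The sub-segment with the larger slope becomes the predicted q2
    (higher-quality) choice and the other the predicted q1 (more annoying)
    choice.  Abstains on both when either sub-segment has fewer than
    ``min_frames`` frames, when the slopes differ by at most
    ``slope_tie_epsilon``, or — in strict mode — when the slopes share a
    sign.
    """
    slopes = _segment_slopes(seg, min_frames, attention_filter)
    idx = seg.comparison.index
    if slopes is None:
        return SimulatedChoice(idx, "abstain", "abstain", float("nan"), float("nan"))
    s1, s2 = slopes
    tie = abs(s1 - s2) <= slope_tie_epsilon
    if tie or (require_opposite_signs and s1 * s2 > 0):
        return SimulatedChoice(idx, "abstain", "abstain", s1, s2)
    if s2 > s1:
        return SimulatedChoice(idx, "first", "second", s1, s2)
    return SimulatedChoice(idx, "second", "first", s1, s2)


_ANSWER_CODE = {"first": -1.0, "second": 1.0}


def juror_answer_correlation(
    segments: list[ComparisonSegment],
    question: str,
    attention_filter: bool = False,
    min_frames: int = 5,
    slope_tie_epsilon: float = 0.0,
    trend_encoding: str = "sign",
) -> tuple[float, int]:
    """Spearman correlation between a juror's answers and their valence trends.

    For each comparison with a recorded (non-``none``) answer and usable
    trend fits, the answer is encoded ±1 (+1 = chose second) and correlated
    against the trend encoding: the slope difference ``second − first``,
    negated for q1 so a criterion-consistent juror scores positive, taken
    either as its sign (default, the simulated choice) or as the raw
    difference.  With ``attention_filter`` the trends are refitted on
    attentive frames only and comparisons left with fewer than
    ``min_frames`` attentive frames in either sub-segment are dropped.

    Returns ``(rho, n_comparisons)``; ``rho`` is NaN when fewer than three
    usable comparisons remain or when either vector is constant.
    """
    if question not in ("q1", "q2"):
        raise ValueError(f"question must be 'q1' or 'q2', got {question!r}")
    if trend_encoding not in ("sign", "difference"):
        raise ValueError(f"unknown trend_encoding {trend_encoding!r}")
    x, y = [], []
    for seg in segments:
        answer = seg.answers.q1_choice if question == "q1" else seg.answers.q2_choice
        if answer == "none":
            continue
        slopes = _segment_slopes(seg, min_frames, attention_filter)
        if slopes is None:
            continue
        diff = slopes[1] - slopes[0]
        if abs(diff) <= slope_tie_epsilon:
            continue
        if question == "q1":
            diff = -diff
        x.append(np.sign(diff) if trend_encoding == "sign" else diff)
        y.append(_ANSWER_CODE[answer])
    n = len(x)
    if n < 3:
        return float("nan"), n
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), n
    rho = stats.spearmanr(x, y).statistic
    return float(rho), n


def juror_reliability(
    juror_id: str,
    segments: list[ComparisonSegment],
    min_frames: int = 5,
    slope_tie_epsilon: float = 0.0,
    trend_encoding: str = "sign",
) -> JurorReliability:
    """Both questions, with and without the attention filter, for one juror."""
    kw = dict(
        min_frames=min_frames,
        slope_tie_epsilon=slope_tie_epsilon,
        trend_encoding=trend_encoding,
    )
    rho_q1_all, n_all = juror_answer_correlation(segments, "q1", False, **kw)
    rho_q2_all, _ = juror_answer_correlation(segments, "q2", False, **kw)
    rho_q1_f, n_f = juror_answer_correlation(segments, "q1", True, **kw)
    rho_q2_f, _ = juror_answer_correlation(segments, "q2", True, **kw)
    return JurorReliability(
        juror_id=juror_id,
        rho_q1_all=rho_q1_all,
        rho_q2_all=rho_q2_all,
        rho_q1_filtered=rho_q1_f,
        rho_q2_filtered=rho_q2_f,
        n_comparisons_all=n_all,
        n_comparisons_filtered=n_f,
    )


def correlation_threshold_curve(
    cohort: list[JurorReliability],
    thresholds: np.ndarray | list[float],
    question: str = "q2",
) -> pd.DataFrame:
    """Count jurors whose correlation clears each threshold, per variant.

    For every threshold τ the count of jurors with ``rho >= τ`` is reported
    for the unfiltered and the attention-filtered correlations (NaN
    correlations never count).  Counts are non-increasing in τ.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if question not in ("q1", "q2"):
        raise ValueError(f"question must be 'q1' or 'q2', got {question!r}")
    rho_all = np.array(
        [getattr(j, f"rho_{question}_all") for j in cohort], dtype=float
    )
    rho_f = np.array(
        [getattr(j, f"rho_{question}_filtered") for j in cohort], dtype=float
    )
    taus = np.asarray(thresholds, dtype=float)
    rows = [
        {
            "threshold": float(tau),
            "n_all": int(np.sum(rho_all >= tau)),
            "n_filtered": int(np.sum(rho_f >= tau)),
        }
        for tau in taus
    ]
    return pd.DataFrame(rows)
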