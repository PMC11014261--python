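"""Juror-session data model: frame stream, AB–BA schedule, answers, cleaning.

A listening jury test presents every unordered pair of stimulus sounds
twice, once in each order (AB–BA repetition), so ``n`` sounds yield
``n·(n−1)`` pairwise comparisons — 42 for the seven-sound design.  During
each comparison the juror hears two sub-segments (sound A then sound B) and
afterwards answers two forced-choice questions: which sound was more
annoying (q1) and which sounded like the higher-quality car (q2).

Frames are kept as a pandas DataFrame with one row per video frame:
``timestamp_s``, the six emotion percentage columns, optional
``neutral_pct``, ``attention`` and the derived ``valence``/``engagement``
columns.  Time windows are half-open ``[start, end)`` in seconds from
session start.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emotions import EMOTIONS, engagement_array, valence_array

__all__ = [
    "EMOTION_COLUMNS",
    "PERIODS",
    "STATES",
    "CHOICES",
    "Comparison",
    "ComparisonSchedule",
    "AnswerRecord",
    "QuestionnaireResponse",
    "ComparisonSegment",
    "InsufficientDataError",
    "build_schedule",
    "attach_metrics",
    "clean_frames",
    "smooth_series",
    "attention_band",
    "segment_frames",
]

EMOTION_COLUMNS = tuple(f"{name}_pct" for name in EMOTIONS)
PERIODS = ("beginning", "during", "end")
STATES = (
    "fully_focused",
    "actively_involved",
    "partially_focused",
    "distracted",
    "feeling_bored",
    "heavy_eyed",
    "mentally_fatigued",
)
CHOICES = ("first", "second", "none")


class InsufficientDataError(ValueError):
    """Too few usable frames or comparisons for the requested statistic."""


@dataclass(frozen=True)
class Comparison:
    """One AB pair in the schedule, with its two half-open play windows."""

    index: int
    sound_first: str
    sound_second: str
    t_start_first: float
    t_end_first: float
    t_start_second: float
    t_end_second: float


@dataclass(frozen=True)
class ComparisonSchedule:
    sounds: tuple[str, ...]
    comparisons: tuple[Comparison, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "comparison_index": c.index,
                    "sound_first": c.sound_first,
                    "sound_second": c.sound_second,
                    "t_start_first": c.t_start_first,
                    "t_end_first": c.t_end_first,
                    "t_start_second": c.t_start_second,
                    "t_end_second": c.t_end_second,
                }
                for c in self.comparisons
            ]
        )

    @property
    def t_end(self) -> float:
        return max((c.t_end_second for c in self.comparisons), default=0.0)


@dataclass(frozen=True)
class AnswerRecord:
    """A juror's two answers after one comparison; 'none' means no choice."""

    comparison_index: int
    q1_choice: str = "none"
    q2_choice: str = "none"

    def __post_init__(self) -> None:
        for choice in (self.q1_choice, self.q2_choice):
            if choice not in CHOICES:
                raise ValueError(f"choice must be one of {CHOICES}, got {choice!r}")


@dataclass(frozen=True)
class QuestionnaireResponse:
    """Self-reported concentration state for one test period."""

    period: str
    state: str

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValueError(f"period must be one of {PERIODS}, got {self.period!r}")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")


@dataclass
class ComparisonSegment:
    """Frames of one comparison split into its two sound sub-segments."""

    comparison: Comparison
    frames_first: pd.DataFrame
    frames_second: pd.DataFrame
    answers: AnswerRecord

    @property
    def usable(self) -> bool:
        return len(self.frames_first) > 0 and len(self.frames_second) > 0


def build_schedule(
    sounds: list[str] | tuple[str, ...],
    segment_duration: float = 10.0,
    gap: float = 1.0,
    start: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ComparisonSchedule:
    """Build the AB–BA comparison schedule for a list of sounds.

    All unordered pairs appear in lexicographic list order as AB, followed
    by the BA repetitions; pass ``rng`` to shuffle the presentation order.
    Play windows are laid out sequentially: each comparison occupies two
    ``segment_duration`` windows back to back, with ``gap`` seconds before
    the next pair.
    """
    sounds = tuple(sounds)
    if len(set(sounds)) != len(sounds):
        raise ValueError("duplicate sound identifiers in schedule")
    if segment_duration <= 0 or gap < 0:
        raise ValueError("durations must be positive and gap non-negative")
    if len(sounds) < 2:
        warnings.warn("fewer than two sounds: empty schedule", stacklevel=2)
        return ComparisonSchedule(sounds=sounds, comparisons=())

    ab = list(itertools.combinations(sounds, 2))
    ordered = ab + [(b, a) for (a, b) in ab]
    if rng is not None:
        ordered = [ordered[i] for i in rng.permutation(len(ordered))]

    comparisons = []
    t = start
    for k, (first, second) in enumerate(ordered):
        comparisons.append(
            Comparison(
                index=k,
                sound_first=first,
                sound_second=second,
                t_start_first=t,
                t_end_first=t + segment_duration,
                t_start_second=t + segment_duration,
                t_end_second=t + 2 * segment_duration,
            )
        )
        t += 2 * segment_duration + gap
    return ComparisonSchedule(sounds=sounds, comparisons=tuple(comparisons))


def attach_metrics(frames: pd.DataFrame) -> pd.DataFrame:
    """Add ``valence`` and ``engagement`` columns derived from the emotion
    percentage columns; rows with missing emotions get NaN metrics."""
    out = frames.copy()
    emo = out[list(EMOTION_COLUMNS)].to_numpy(dtype=float)
    out["valence"] = valence_array(emo)
    out["engagement"] = engagement_array(emo)
    return out


def clean_frames(
    frames: pd.DataFrame, window: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Drop unusable frames: missing emotion data, missing attention value,
    or timestamps outside the session window ``[t_start, t_end]``.

    Order is preserved and the operation is idempotent.  An empty result is
    allowed (downstream operations tolerate empty sessions) but warned about.
    """
    mask = frames[list(EMOTION_COLUMNS)].notna().all(axis=1)
    if "attention" in frames.columns:
        mask &= frames["attention"].notna()
    else:
        mask &= False
    if window is not None:
        t = frames["timestamp_s"]
        mask &= (t >= window[0]) & (t <= window[1])
    out = frames.loc[mask].copy()
    if len(out) == 0:
        warnings.warn("no usable frames after cleaning (empty session)", stacklevel=2)
    return out


def smooth_series(values, window_frames: int) -> np.ndarray:
    """Centered moving average with truncated edges.

    Each output sample is the mean of the input samples in the centered
    window of nominal length ``window_frames``, truncated at the series
    boundaries (no padding); for even windows the extra sample is taken on
    the trailing side.  Boolean attention series smoothed this way yield a
    continuous attentive fraction in [0, 1].
    """
    if window_frames < 1:
        raise ValueError(f"window_frames must be >= 1, got {window_frames}")
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n == 0:
        return x.copy()
    left = (window_frames - 1) // 2
    right = window_frames // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, n - 1) + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


def attention_band(smoothed_attention):
    """Classify a smoothed attention value into the plotting bands:
    ``> 0.8`` attentive, ``< 0.2`` inattentive, otherwise intermediate
    (strict inequalities, so 0.8 and 0.2 are both intermediate)."""
    arr = np.asarray(smoothed_attention, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("smoothed attention values must lie in [0, 1]")
    bands = np.where(arr > 0.8, "attentive", np.where(arr < 0.2, "inattentive", "intermediate"))
    if np.isscalar(smoothed_attention) or np.ndim(smoothed_attention) == 0:
        return str(bands)
    return bands


def segment_frames(
    frames: pd.DataFrame,
    schedule: ComparisonSchedule,
    answers: list[AnswerRecord] | None = None,
) -> list[ComparisonSegment]:
    """Split cleaned frames into per-comparison sound sub-segments.

    Frames are assigned by half-open windows ``[start, end)`` so each frame
    lands in at most one sub-segment.  Comparisons without a recorded answer
    get an all-``none`` :class:`AnswerRecord`.  Segments where either
    sub-segment is empty are returned with ``usable == False``.
    """
    answers = answers or []
    by_index = {}
    known = {c.index for c in schedule.comparisons}
    for a in answers:
        if a.comparison_index not in known:
            raise ValueError(f"answer references unknown comparison {a.comparison_index}")
        by_index[a.comparison_index] = a

    t = frames["timestamp_s"].to_numpy(dtype=float)
    segments = []
    for comp in schedule.comparisons:
        first = frames.loc[(t >= comp.t_start_first) & (t < comp.t_end_first)]
        second = frames.loc[(t >= comp.t_start_second) & (t < comp.t_end_second)]
        segments.append(
            ComparisonSegment(
                comparison=comp,
                frames_first=first,
                frames_second=second,
                answers=by_index.get(comp.index, AnswerRecord(comp.index)),
            )
        )
    return segments
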