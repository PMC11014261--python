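"""Per-frame valence and engagement from Ekman emotion probabilities.

A facial-expression recognition front end emits, for every video frame, a
probability for each of Ekman's six universal emotions (happiness, surprise,
sadness, anger, fear, disgust), softmax-normalised so the percentages sum
to 100.  Two scalar summaries are derived per frame:

* **valence** — signed positivity of the expressed state,
  ``happiness − sadness − anger − fear − disgust``, in [−100, 100];
* **engagement** — deviation from neutrality,
  ``happiness + surprise + anger + fear − sadness``, reported in [0, 100].

The engagement formula can be negative (e.g. pure sadness gives −100); the
reported value is clipped at zero while the raw value stays retrievable.
An optional ``neutral`` channel may be present in the data; it counts toward
the sum-to-100 constraint but enters neither formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "EMOTIONS",
    "VALENCE_COEFFS",
    "ENGAGEMENT_COEFFS",
    "EmotionVector",
    "EmotionMetrics",
    "DegenerateInputError",
    "normalize_probabilities",
    "valence",
    "engagement",
    "engagement_raw",
    "metrics",
    "valence_array",
    "engagement_array",
    "metric_extrema",
]

#: Canonical channel order used throughout the package.
EMOTIONS = ("happiness", "surprise", "sadness", "anger", "fear", "disgust")

#: Linear coefficients of the valence formula, in EMOTIONS order.
VALENCE_COEFFS: Mapping[str, float] = {
    "happiness": 1.0,
    "surprise": 0.0,
    "sadness": -1.0,
    "anger": -1.0,
    "fear": -1.0,
    "disgust": -1.0,
}

#: Linear coefficients of the engagement formula (before clipping).
ENGAGEMENT_COEFFS: Mapping[str, float] = {
    "happiness": 1.0,
    "surprise": 1.0,
    "sadness": -1.0,
    "anger": 1.0,
    "fear": 1.0,
    "disgust": 0.0,
}

_SUM_TOL = 1e-6


class DegenerateInputError(ValueError):
    """Raised when an emotion score vector carries no information (all zero)."""


@dataclass(frozen=True)
class EmotionVector:
    """One frame's emotion percentages on the 100-simplex.

    Components are non-negative and (including the optional neutral channel)
    sum to at most 100 + tolerance; a vector coming out of
    :func:`normalize_probabilities` sums to exactly 100.
    """

    happiness: float
    surprise: float
    sadness: float
    anger: float
    fear: float
    disgust: float
    neutral: float | None = None

    def __post_init__(self) -> None:
        comps = self.as_array()
        if self.neutral is not None:
            comps = np.append(comps, self.neutral)
        if not np.all(np.isfinite(comps)):
            raise ValueError("emotion components must be finite")
        if np.any(comps < 0):
            raise ValueError(f"emotion components must be non-negative, got {comps}")
        if comps.sum() > 100.0 + _SUM_TOL:
            raise ValueError(
                f"emotion components sum to {comps.sum():.6f} > 100"
            )

    def as_array(self) -> np.ndarray:
        """Six components in :data:`EMOTIONS` order (neutral excluded)."""
        return np.array(
            [self.happiness, self.surprise, self.sadness,
             self.anger, self.fear, self.disgust],
            dtype=float,
        )

    @property
    def total(self) -> float:
        extra = self.neutral if self.neutral is not None else 0.0
        return float(self.as_array().sum() + extra)


@dataclass(frozen=True)
class EmotionMetrics:
    """Derived scalar metrics for one frame."""

    valence: float
    engagement_raw: float

    @property
    def engagement(self) -> float:
        return max(0.0, self.engagement_raw)


def normalize_probabilities(
    raw_scores: Sequence[float] | Iterable[float],
    neutral: float | None = None,
) -> EmotionVector:
    """Rescale non-negative raw scores so all channels sum to 100.

    ``raw_scores`` is the six-channel vector in :data:`EMOTIONS` order;
    ``neutral``, if given, participates in the normalisation as a seventh
    channel.  Raises :class:`DegenerateInputError` on an all-zero input and
    ``ValueError`` on a negative score.
    """
    arr = np.asarray(list(raw_scores), dtype=float)
    if arr.shape != (len(EMOTIONS),):
        raise ValueError(f"expected {len(EMOTIONS)} emotion scores, got {arr.shape}")
    full = arr if neutral is None else np.append(arr, float(neutral))
    if np.any(full < 0):
        raise ValueError(f"raw scores must be non-negative, got {full}")
    total = full.sum()
    if total <= 0:
        raise DegenerateInputError("all raw emotion scores are zero")
    full = full * (100.0 / total)
    kwargs = dict(zip(EMOTIONS, full[: len(EMOTIONS)]))
    if neutral is not None:
        kwargs["neutral"] = float(full[-1])
    return EmotionVector(**kwargs)


def _coeff_vector(coeffs: Mapping[str, float]) -> np.ndarray:
    return np.array([coeffs[name] for name in EMOTIONS], dtype=float)


def valence(e: EmotionVector) -> float:
    """Eq.-style valence score in [−100, 100]; surprise and neutral drop out."""
    return float(_coeff_vector(VALENCE_COEFFS) @ e.as_array())


def engagement_raw(e: EmotionVector) -> float:
    """Unclipped engagement score in [−100, 100]."""
    return float(_coeff_vector(ENGAGEMENT_COEFFS) @ e.as_array())


def engagement(e: EmotionVector) -> float:
    """Engagement score clipped to [0, 100]."""
    return max(0.0, engagement_raw(e))


def metrics(e: EmotionVector) -> EmotionMetrics:
    """Both derived metrics for one frame."""
    return EmotionMetrics(valence=valence(e), engagement_raw=engagement_raw(e))


def valence_array(emotion_pct: np.ndarray) -> np.ndarray:
    """Vectorised valence for an (n, 6) percentage array in EMOTIONS order."""
    return np.asarray(emotion_pct, dtype=float) @ _coeff_vector(VALENCE_COEFFS)


def engagement_array(emotion_pct: np.ndarray, clip: bool = True) -> np.ndarray:
    """Vectorised engagement for an (n, 6) percentage array."""
    raw = np.asarray(emotion_pct, dtype=float) @ _coeff_vector(ENGAGEMENT_COEFFS)
    return np.maximum(raw, 0.0) if clip else raw


def metric_extrema(
    coeffs: Mapping[str, float] | Sequence[float],
    resolution: float = 1.0,
    total: float = 100.0,
) -> tuple[float, float, int]:
    """Exhaustive grid search of a linear metric over the emotion simplex.

    Searches all percentage vectors with non-negative components summing to
    at most ``total`` on a grid of step ``resolution``.  Because the metric
    is linear and coordinates sharing a coefficient are interchangeable, the
    search is run over the *group totals* (one total per distinct
    coefficient value) on the same grid: every full-grid point maps to a
    group-total point with the same metric value, and every group-total
    point is realised by a full-grid point (put the whole group total on one
    coordinate), so the extrema are identical to a full six-dimensional
    sweep while the grid stays small.

    Returns ``(minimum, maximum, n_grid_points)`` where ``n_grid_points``
    counts the reduced grid points evaluated.
    """
    if isinstance(coeffs, Mapping):
        c = _coeff_vector(coeffs)
    else:
        c = np.asarray(list(coeffs), dtype=float)
    uniq = np.unique(c)
    steps = int(round(total / resolution))

    lo, hi, count = np.inf, -np.inf, 0
    # recursively enumerate group totals t_1..t_k with sum <= total
    def recurse(idx: int, budget_steps: int, acc: float) -> None:
        nonlocal lo, hi, count
        if idx == len(uniq) - 1:
            t = np.arange(budget_steps + 1) * resolution
            vals = acc + uniq[idx] * t
            lo = min(lo, vals.min())
            hi = max(hi, vals.max())
            count += len(vals)
            return
        for s in range(budget_steps + 1):
            recurse(idx + 1, budget_steps - s, acc + uniq[idx] * s * resolution)

    recurse(0, steps, 0.0)
    return float(lo), float(hi), count
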