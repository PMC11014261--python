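"""Frame-level attention classification from 68-point facial landmarks.

Head pose is proxied by ratios of Euclidean distances between landmark
pairs of the standard 68-point annotation scheme (1-based, jawline 1–17,
nose bridge 28–31, eyes 37–48):

* ``yaw`` — |dist(2,31) / dist(31,16)| folded into (0, 1] by taking the
  reciprocal when > 1; near 1 for a frontal face, small for a turned head.
* ``pitch`` — dist(28,31) / dist(37,40), falling back to dist(43,46) when
  the first eye width is degenerate.
* ``ear`` — the eye aspect ratio of Soukupová & Čech blink detection:
  (‖p2−p6‖ + ‖p3−p5‖) / (2‖p1−p4‖) over an eye's six ordered landmarks,
  averaged over both eyes; near zero when the eyes are closed.

A frame is *face-attentive* when the yaw ratio clears its threshold and the
pitch gate does not fire; in the default ``ear_guarded`` mode the pitch gate
only fires together with a low EAR, so ordinary blinks (low EAR, normal
pitch) never flag inattention.  Combined attention additionally requires
the horizontal gaze-screen coordinate to fall strictly inside a window on
the monitor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LandmarkSet",
    "HeadPoseFeatures",
    "GazeSample",
    "AttentionConfig",
    "DegenerateLandmarkError",
    "landmark_distance",
    "yaw_ratio",
    "pitch_ratio",
    "eye_aspect_ratio",
    "head_pose_features",
    "face_attention",
    "combined_attention",
    "classify_frames",
]

# 1-based landmark indices of the distance pairs used for head pose
PAIR_A = (2, 31)   # left jaw to nose tip
PAIR_B = (31, 16)  # nose tip to right jaw
PAIR_C = (28, 31)  # nose bridge length
PAIR_D = (37, 40)  # left eye width
PAIR_E = (43, 46)  # right eye width
LEFT_EYE = (37, 38, 39, 40, 41, 42)
RIGHT_EYE = (43, 44, 45, 46, 47, 48)

_EPS = 1e-9


class DegenerateLandmarkError(ValueError):
    """Landmark geometry is degenerate (zero reference distance); the frame
    should be treated as no-face and dropped during cleaning."""


@dataclass(frozen=True)
class LandmarkSet:
    """One frame's 68 facial landmarks in pixel coordinates, 1-based indexing."""

    points: np.ndarray  # (68, 2)
    frame_timestamp: float = 0.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (68, 2):
            raise ValueError(f"expected 68 (x, y) landmarks, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def point(self, i: int) -> np.ndarray:
        """Landmark ``i`` using the 1-based convention of the 68-point scheme."""
        if not 1 <= i <= 68:
            raise ValueError(f"landmark index must be in 1..68, got {i}")
        return self.points[i - 1]


@dataclass(frozen=True)
class HeadPoseFeatures:
    """Distances and ratios extracted from one landmark set."""

    dist_a: float
    dist_b: float
    dist_c: float
    dist_d: float
    dist_e: float
    yaw: float
    pitch: float
    ear: float


@dataclass(frozen=True)
class GazeSample:
    """Gaze point on the screen in cm, origin at the top-left corner."""

    x: float = float("nan")
    y: float = float("nan")
    available: bool = True

    def __post_init__(self) -> None:
        if self.available and not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("available gaze sample must have finite coordinates")


@dataclass(frozen=True)
class AttentionConfig:
    """Thresholds and modes of the attention classifier.

    ``pitch_gate_mode='ear_guarded'`` (default) flags inattention on high
    pitch only when the EAR is simultaneously low, so blinks do not produce
    false negatives; ``'literal'`` requires pitch strictly below its
    threshold regardless of EAR.  Boundary semantics follow the printed
    comparisons: yaw exactly at threshold counts attentive, pitch exactly at
    threshold does not fire the guarded gate, gaze bounds are strict.
    """

    yaw_threshold: float = 0.4
    pitch_threshold: float = 5.0
    ear_threshold: float = 0.10
    gaze_x_min: float = 1.0
    gaze_x_max: float = 25.0
    pitch_gate_mode: str = "ear_guarded"
    gaze_missing_policy: str = "pass_through"

    def __post_init__(self) -> None:
        if min(self.yaw_threshold, self.pitch_threshold, self.ear_threshold) <= 0:
            raise ValueError("thresholds must be positive")
        if not self.gaze_x_min < self.gaze_x_max:
            raise ValueError("gaze_x_min must be below gaze_x_max")
        if self.pitch_gate_mode not in ("ear_guarded", "literal"):
            raise ValueError(f"unknown pitch_gate_mode {self.pitch_gate_mode!r}")
        if self.gaze_missing_policy not in ("pass_through", "inattentive"):
            raise ValueError(f"unknown gaze_missing_policy {self.gaze_missing_policy!r}")


def landmark_distance(lm: LandmarkSet, i: int, j: int) -> float:
    """Euclidean pixel distance between landmarks ``i`` and ``j`` (1-based)."""
    return float(np.linalg.norm(lm.point(i) - lm.point(j)))


def yaw_ratio(lm: LandmarkSet) -> float:
    """Horizontal head-rotation proxy in (0, 1]."""
    a = landmark_distance(lm, *PAIR_A)
    b = landmark_distance(lm, *PAIR_B)
    if a <= _EPS or b <= _EPS:
        raise DegenerateLandmarkError("zero jaw-to-nose distance; treating as no face")
    r = abs(a / b)
    return r if r <= 1.0 else 1.0 / r


def pitch_ratio(lm: LandmarkSet) -> float:
    """Vertical head-rotation proxy: nose-bridge length over eye width."""
    c = landmark_distance(lm, *PAIR_C)
    d = landmark_distance(lm, *PAIR_D)
    e = landmark_distance(lm, *PAIR_E)
    denom = d if d > _EPS else e
    if denom <= _EPS:
        raise DegenerateLandmarkError("both eye widths degenerate; treating as no face")
    return abs(c / denom)


def _single_ear(pts: np.ndarray, idx: Sequence[int]) -> float | None:
    p = pts[np.asarray(idx) - 1]
    width = np.linalg.norm(p[0] - p[3])
    if width <= _EPS:
        return None
    return float((np.linalg.norm(p[1] - p[5]) + np.linalg.norm(p[2] - p[4])) / (2.0 * width))


def eye_aspect_ratio(lm: LandmarkSet) -> float:
    """Mean eye aspect ratio over both eyes, with single-eye fallback."""
    ears = [e for e in (_single_ear(lm.points, LEFT_EYE),
                        _single_ear(lm.points, RIGHT_EYE)) if e is not None]
    if not ears:
        raise DegenerateLandmarkError("zero eye width in both eyes; treating as no face")
    return float(np.mean(ears))


def head_pose_features(lm: LandmarkSet) -> HeadPoseFeatures:
    """All pose distances and ratios for one landmark set."""
    return HeadPoseFeatures(
        dist_a=landmark_distance(lm, *PAIR_A),
        dist_b=landmark_distance(lm, *PAIR_B),
        dist_c=landmark_distance(lm, *PAIR_C),
        dist_d=landmark_distance(lm, *PAIR_D),
        dist_e=landmark_distance(lm, *PAIR_E),
        yaw=yaw_ratio(lm),
        pitch=pitch_ratio(lm),
        ear=eye_aspect_ratio(lm),
    )


def _face_attention_arrays(
    yaw: np.ndarray, pitch: np.ndarray, ear: np.ndarray, cfg: AttentionConfig
) -> np.ndarray:
    yaw_ok = yaw >= cfg.yaw_threshold
    if cfg.pitch_gate_mode == "ear_guarded":
        gate = (pitch > cfg.pitch_threshold) & (ear < cfg.ear_threshold)
        return yaw_ok & ~gate
    return yaw_ok & (pitch < cfg.pitch_threshold)


def face_attention(
    f: HeadPoseFeatures, cfg: AttentionConfig | None = None
) -> bool:
    """Head-pose attention decision for one frame."""
    cfg = cfg or AttentionConfig()
    return bool(
        _face_attention_arrays(
            np.asarray(f.yaw), np.asarray(f.pitch), np.asarray(f.ear), cfg
        )
    )


def combined_attention(
    face_attn: bool, gaze: GazeSample | None, cfg: AttentionConfig | None = None
) -> bool:
    """Face attention gated by the horizontal gaze window.

    Gaze y is deliberately ignored (only the x direction is reliable enough
    to threshold).  A missing gaze sample is handled by
    ``cfg.gaze_missing_policy``.
    """
    cfg = cfg or AttentionConfig()
    if gaze is None or not gaze.available:
        if cfg.gaze_missing_policy == "pass_through":
            return bool(face_attn)
        return False
    return bool(face_attn) and (cfg.gaze_x_min < gaze.x < cfg.gaze_x_max)


def classify_frames(
    landmarks: np.ndarray,
    gaze_x: np.ndarray | None = None,
    cfg: AttentionConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised attention classification for a whole frame stream.

    Parameters
    ----------
    landmarks
        Array of shape (n, 68, 2), pixel coordinates, landmark order per the
        1-based 68-point convention.
    gaze_x
        Optional (n,) horizontal gaze coordinates in cm; NaN marks a missing
        sample.
    cfg
        Thresholds; defaults to :class:`AttentionConfig`.

    Returns
    -------
    attention, valid
        Two (n,) boolean arrays.  ``valid`` is False on frames with
        degenerate geometry (zero reference distances); their ``attention``
        entry is False and should be treated as missing downstream.
    """
    cfg = cfg or AttentionConfig()
    pts = np.asarray(landmarks, dtype=float)
    if pts.ndim != 3 or pts.shape[1:] != (68, 2):
        raise ValueError(f"expected (n, 68, 2) landmark array, got {pts.shape}")

    def dist(i: int, j: int) -> np.ndarray:
        return np.linalg.norm(pts[:, i - 1] - pts[:, j - 1], axis=1)

    a, b = dist(*PAIR_A), dist(*PAIR_B)
    c, d, e = dist(*PAIR_C), dist(*PAIR_D), dist(*PAIR_E)
    valid = (a > _EPS) & (b > _EPS)

    with np.errstate(divide="ignore", invalid="ignore"):
        yaw = np.abs(a / np.where(b > _EPS, b, np.nan))
        yaw = np.where(yaw > 1.0, 1.0 / yaw, yaw)

        pitch_den = np.where(d > _EPS, d, e)
        valid &= pitch_den > _EPS
        pitch = np.abs(c / np.where(pitch_den > _EPS, pitch_den, np.nan))

        def eye_ear(idx: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
            p = pts[:, np.asarray(idx) - 1]
            width = np.linalg.norm(p[:, 0] - p[:, 3], axis=1)
            num = (np.linalg.norm(p[:, 1] - p[:, 5], axis=1)
                   + np.linalg.norm(p[:, 2] - p[:, 4], axis=1))
            ok = width > _EPS
            return np.where(ok, num / np.where(ok, 2.0 * width, np.nan), np.nan), ok

        ear_l, ok_l = eye_ear(LEFT_EYE)
        ear_r, ok_r = eye_ear(RIGHT_EYE)
        n_eyes = ok_l.astype(float) + ok_r.astype(float)
        valid &= n_eyes > 0
        ear = (np.where(ok_l, ear_l, 0.0) + np.where(ok_r, ear_r, 0.0)) / np.where(
            n_eyes > 0, n_eyes, np.nan
        )

        attn = _face_attention_arrays(yaw, pitch, ear, cfg)

    if gaze_x is not None:
        gx = np.asarray(gaze_x, dtype=float)
        have_gaze = np.isfinite(gx)
        in_window = have_gaze & (gx > cfg.gaze_x_min) & (gx < cfg.gaze_x_max)
        if cfg.gaze_missing_policy == "pass_through":
            attn = attn & np.where(have_gaze, in_window, True)
        else:
            attn = attn & in_window

    return attn & valid, valid
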