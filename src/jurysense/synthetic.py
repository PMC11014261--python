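"""Synthetic jury-test sessions with the statistical structure the analysis assumes.

The study's raw recordings are private, so every pipeline stage is
exercised against generated data instead:

* a fixed, bilaterally symmetric 3-D face template whose rigid rotation and
  orthographic projection produce 68-point landmark streams (so the
  attention classifier, not a label, decides each frame);
* a two-state attentive/inattentive dwell process with period-specific
  rates emulating the session-long decline in concentration;
* emotion percentage series realising a piecewise-linear latent valence
  trend per sound sub-segment through the happiness/sadness channel, with
  Gaussian frame noise and extra trend-destroying noise on inattentive
  frames;
* answers that follow the slope criterion (larger slope = higher quality,
  smaller = more annoying) with a configurable consistency probability;
* questionnaire states derived from the realised per-period attention rate
  through fixed cut-points.

Generation is a pure function of the spec: the same seed reproduces a
session bit for bit.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import session as sm
from .emotions import EMOTIONS
from .geometry import AttentionConfig, LandmarkSet, classify_frames
from .questionnaire import AttentionSession
from .session import (
    AnswerRecord,
    ComparisonSchedule,
    PERIODS,
    QuestionnaireResponse,
    attach_metrics,
    build_schedule,
)

__all__ = [
    "FACE_TEMPLATE",
    "TEMPLATE_EAR",
    "FacePoseModel",
    "SyntheticSessionSpec",
    "SyntheticSession",
    "synth_landmarks",
    "synth_landmark_stream",
    "synth_attention_states",
    "synth_emotion_series",
    "synth_session",
    "synth_cohort",
]


def _build_face_template() -> np.ndarray:
    """Fixed 68-point neutral face in model units (x right, y down, z toward
    the camera), bilaterally symmetric about x = 0.

    Only the jaw anchors (2, 16), nose bridge (28–31) and eye hexads
    (37–48) carry geometric meaning for the classifier; the remaining
    points are plausible filler so the full landmark convention is
    populated.
    """
    pts = np.zeros((68, 3))
    # jawline 1-17: half-ellipse from left ear over the chin to right ear
    t = np.arange(17) * math.pi / 16.0
    pts[0:17, 0] = -6.5 * np.cos(t)
    pts[0:17, 1] = 7.0 * np.sin(t)
    pts[0:17, 2] = -1.2
    # brows 18-27
    bx = np.linspace(-5.6, -1.9, 5)
    pts[17:22] = np.c_[bx, -4.4 - 0.5 * np.sin(np.linspace(0, math.pi, 5)), np.full(5, 0.5)]
    pts[22:27] = pts[17:22][::-1] * np.array([-1.0, 1.0, 1.0])
    # nose bridge 28-31 and nostril row 32-36
    pts[27:31] = [(0.0, -2.5, 1.0), (0.0, -1.6, 1.3), (0.0, -0.8, 1.6), (0.0, 0.0, 2.0)]
    pts[31:36] = np.c_[np.linspace(-1.2, 1.2, 5), np.full(5, 0.9), np.full(5, 1.0)]
    # eyes 37-48: corners at the lid line, upper/lower lids offset 0.4
    pts[36:42] = [(-4.2, -2.5, 0.0), (-3.6, -2.9, 0.0), (-2.4, -2.9, 0.0),
                  (-1.8, -2.5, 0.0), (-2.4, -2.1, 0.0), (-3.6, -2.1, 0.0)]
    pts[42:48] = [(1.8, -2.5, 0.0), (2.4, -2.9, 0.0), (3.6, -2.9, 0.0),
                  (4.2, -2.5, 0.0), (3.6, -2.1, 0.0), (2.4, -2.1, 0.0)]
    # mouth: outer ring 49-60, inner ring 61-68, center (0, 4.5)
    a_out = np.concatenate([np.linspace(math.pi, 0.0, 7),        # 49-55 upper
                            np.linspace(math.pi / 6, 5 * math.pi / 6, 5)])  # 56-60 lower
    sign = np.concatenate([-np.ones(7), np.ones(5)])
    pts[48:60] = np.c_[2.2 * np.cos(a_out) * -1.0,
                       4.5 + sign * 1.0 * np.sin(a_out), np.full(12, 0.8)]
    a_in = np.concatenate([np.linspace(math.pi, 0.0, 5),          # 61-65 upper
                           np.linspace(math.pi / 4, 3 * math.pi / 4, 3)])   # 66-68 lower
    sign_in = np.concatenate([-np.ones(5), np.ones(3)])
    pts[60:68] = np.c_[1.4 * np.cos(a_in) * -1.0,
                       4.5 + sign_in * 0.4 * np.sin(a_in), np.full(8, 0.8)]
    pts.setflags(write=False)
    return pts


FACE_TEMPLATE = _build_face_template()

_EYE_CENTER_Y = -2.5
_UPPER_LIDS = np.array([38, 39, 44, 45]) - 1
_LOWER_LIDS = np.array([41, 42, 47, 48]) - 1
#: EAR of the open-eyed frontal template: (0.8 + 0.8) / (2 * 2.4)
TEMPLATE_EAR = 1.0 / 3.0

#: Base emotion percentages (EMOTIONS order) around which valence trends
#: are injected through the happiness/sadness channel; sums to 100.
BASE_EMOTIONS = np.array([30.0, 15.0, 30.0, 10.0, 5.0, 10.0])
BASE_VALENCE = 30.0 - 30.0 - 10.0 - 5.0 - 10.0  # -25


@dataclass(frozen=True)
class FacePoseModel:
    """Rigid pose and eyelid state applied to the face template."""

    yaw_angle: float = 0.0     # degrees about the vertical axis
    pitch_angle: float = 0.0   # degrees about the horizontal axis
    eye_openness: float = 1.0  # 1 open, 0 closed
    scale: float = 10.0        # pixels per model unit
    translation: tuple[float, float] = (320.0, 240.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.eye_openness <= 1.0:
            raise ValueError("eye_openness must lie in [0, 1]")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def synth_landmark_stream(
    yaw_deg: np.ndarray,
    pitch_deg: np.ndarray,
    eye_openness: np.ndarray,
    scale: float = 10.0,
    translation: tuple[float, float] = (320.0, 240.0),
) -> np.ndarray:
    """Project the template under per-frame poses; returns (n, 68, 2) pixels.

    Eyelid landmarks are scaled toward the lid line by ``eye_openness``
    before the rigid rotation; projection is orthographic along z.
    """
    yaw = np.deg2rad(np.atleast_1d(np.asarray(yaw_deg, dtype=float)))
    pitch = np.deg2rad(np.atleast_1d(np.asarray(pitch_deg, dtype=float)))
    openness = np.atleast_1d(np.asarray(eye_openness, dtype=float))
    n = len(yaw)
    pts = np.broadcast_to(FACE_TEMPLATE, (n, 68, 3)).copy()
    for lids in (_UPPER_LIDS, _LOWER_LIDS):
        pts[:, lids, 1] = _EYE_CENTER_Y + (
            pts[:, lids, 1] - _EYE_CENTER_Y
        ) * openness[:, None]

    cy, sy = np.cos(yaw), np.sin(yaw)
    cp, sp = np.cos(pitch), np.sin(pitch)
    # R = Ry(yaw) @ Rx(pitch), per frame
    rot = np.zeros((n, 3, 3))
    rot[:, 0, 0] = cy
    rot[:, 0, 1] = sy * sp
    rot[:, 0, 2] = sy * cp
    rot[:, 1, 1] = cp
    rot[:, 1, 2] = -sp
    rot[:, 2, 0] = -sy
    rot[:, 2, 1] = cy * sp
    rot[:, 2, 2] = cy * cp
    rotated = np.einsum("nij,npj->npi", rot, pts)
    out = rotated[:, :, :2] * scale + np.asarray(translation)
    return out


def synth_landmarks(pose: FacePoseModel) -> LandmarkSet:
    """One projected landmark set for a single pose."""
    pts = synth_landmark_stream(
        np.array([pose.yaw_angle]),
        np.array([pose.pitch_angle]),
        np.array([pose.eye_openness]),
        scale=pose.scale,
        translation=pose.translation,
    )[0]
    return LandmarkSet(points=pts)


@dataclass(frozen=True)
class SyntheticSessionSpec:
    """Study conditions for one generated juror session.

    Defaults mirror the seven-sound AB–BA design at 14 frames per second
    with 10 s sub-segments, a session-long decline in attentiveness
    (attentive-state probability 0.95 / 0.70 / 0.40 over the three test
    periods), spontaneous blinks, and answers that follow the valence-slope
    criterion with probability ``p_consistent``.
    """

    n_sounds: int = 7
    sound_slopes: tuple[float, ...] | None = None  # valence units per second
    segment_duration: float = 10.0
    gap: float = 1.0
    emotion_noise_sd: float = 2.0       # percentage points per channel
    inattentive_noise_sd: float = 25.0  # sd of the distraction-valence walk
    p_consistent: float = 0.9
    attention_rates: tuple[float, float, float] = (0.95, 0.70, 0.40)
    attention_dwell_frames: float = 42.0  # ~3 s at 14 fps
    blink_rate: float = 0.25              # blinks per second
    blink_duration_frames: int = 3
    frame_rate: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sounds < 2:
            raise ValueError("need at least two sounds")
        if self.frame_rate <= 0 or self.segment_duration <= 0:
            raise ValueError("frame_rate and segment_duration must be positive")
        for p in (self.p_consistent, *self.attention_rates):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probabilities must lie in [0, 1], got {p}")
        if self.sound_slopes is not None and len(self.sound_slopes) != self.n_sounds:
            raise ValueError("sound_slopes length must equal n_sounds")

    @property
    def slopes(self) -> np.ndarray:
        if self.sound_slopes is not None:
            return np.asarray(self.sound_slopes, dtype=float)
        return np.linspace(-2.0, 2.0, self.n_sounds)

    @property
    def sounds(self) -> list[str]:
        return [f"sound_{i + 1}" for i in range(self.n_sounds)]


@dataclass
class SyntheticSession:
    """One generated juror session with every file the pipeline consumes."""

    juror_id: str
    spec: SyntheticSessionSpec
    schedule: ComparisonSchedule
    frames: pd.DataFrame          # classifier-derived attention + metrics
    landmarks: np.ndarray         # (n, 68, 2)
    gaze: pd.DataFrame
    answers: list[AnswerRecord]
    responses: tuple[QuestionnaireResponse, ...]
    latent: pd.DataFrame          # ground truth: attentive_true, target_valence
    manifest: dict

    def attention_record(self) -> AttentionSession:
        """Classifier-attention stream plus self reports, for the
        questionnaire analysis."""
        return AttentionSession(
            juror_id=self.juror_id,
            timestamps=self.frames["timestamp_s"].to_numpy(),
            attention=self.frames["attention"].to_numpy(dtype=float),
            responses=self.responses,
        )


def synth_attention_states(
    n_frames: int,
    rates: tuple[float, float, float],
    dwell_frames: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent attentive/inattentive Boolean stream.

    A two-state Markov chain whose per-period transition probabilities are
    scaled so the stationary attentive probability equals the period's rate
    while state dwells last about ``dwell_frames`` frames; the session is
    split into three equal periods (beginning / during / end).
    """
    edges = np.linspace(0, n_frames, len(rates) + 1).astype(int)
    period_of = np.searchsorted(edges[1:-1], np.arange(n_frames), side="right")
    u = rng.random(n_frames)
    states = np.empty(n_frames, dtype=bool)
    state = bool(u[0] < rates[0]) if n_frames else True
    for k in range(n_frames):
        p = rates[period_of[k]]
        if k > 0:
            leave = (1.0 - p) / dwell_frames if state else p / dwell_frames
            if u[k] < min(leave, 1.0):
                state = not state
        states[k] = state
    return states


def synth_emotion_series(
    spec: SyntheticSessionSpec,
    schedule: ComparisonSchedule,
    timestamps: np.ndarray | None = None,
    inattentive: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Emotion percentage series realising the injected valence trends.

    Within each sound sub-segment the latent valence follows a line with
    the sound's slope, centred on the base valence at the sub-segment
    midpoint; outside any sub-segment it stays at the base.  The line is
    realised by moving mass between happiness and sadness around
    :data:`BASE_EMOTIONS`; Gaussian channel noise (and extra valence-channel
    noise on inattentive frames) is added, components are clipped at zero
    and renormalised to sum to 100.

    Returns ``(timestamps, emotion_pct (n, 6), target_valence)``.
    """
    rng = rng or np.random.default_rng(spec.seed)
    if timestamps is None:
        timestamps = np.arange(0.0, schedule.t_end, 1.0 / spec.frame_rate)
    n = len(timestamps)
    if inattentive is None:
        inattentive = np.zeros(n, dtype=bool)

    slope_by_sound = dict(zip(spec.sounds, spec.slopes))
    half = spec.segment_duration / 2.0
    budget = min(BASE_EMOTIONS[0], BASE_EMOTIONS[2])  # happiness/sadness headroom
    for s, slope in slope_by_sound.items():
        if abs(slope) * half / 2.0 > budget:
            raise ValueError(
                f"slope {slope} for {s} infeasible: would drive happiness or "
                f"sadness below zero within a {spec.segment_duration} s segment"
            )

    target = np.full(n, float(BASE_VALENCE))
    for comp in schedule.comparisons:
        for sound, lo, hi in (
            (comp.sound_first, comp.t_start_first, comp.t_end_first),
            (comp.sound_second, comp.t_start_second, comp.t_end_second),
        ):
            mask = (timestamps >= lo) & (timestamps < hi)
            mid = (lo + hi) / 2.0
            target[mask] = BASE_VALENCE + slope_by_sound[sound] * (timestamps[mask] - mid)

    # Inattentive frames express emotion unrelated to the stimulus: the
    # stimulus-driven trend is replaced by a slowly wandering distraction
    # valence (an AR(1) with ~2 s correlation time), so those frames are
    # trend-destroying rather than merely noisy.
    delta = target - BASE_VALENCE
    if spec.inattentive_noise_sd > 0 and inattentive.any():
        phi = math.exp(-1.0 / (2.0 * spec.frame_rate))
        innov = rng.normal(0.0, spec.inattentive_noise_sd, size=n) * math.sqrt(
            1.0 - phi * phi
        )
        wander = np.empty(n)
        prev = rng.normal(0.0, spec.inattentive_noise_sd)
        for k in range(n):
            prev = phi * prev + innov[k]
            wander[k] = prev
        delta = np.where(inattentive, np.clip(wander, -55.0, 55.0), delta)
    emo = np.tile(BASE_EMOTIONS, (n, 1))
    emo[:, 0] += delta / 2.0   # happiness
    emo[:, 2] -= delta / 2.0   # sadness
    if spec.emotion_noise_sd > 0:
        emo += rng.normal(0.0, spec.emotion_noise_sd, size=emo.shape)
    emo = np.clip(emo, 0.0, None)
    emo *= 100.0 / emo.sum(axis=1, keepdims=True)
    return np.asarray(timestamps, dtype=float), emo, target


_STATE_CUTS = (
    (0.80, "fully_focused"),
    (0.65, "actively_involved"),
    (0.50, "partially_focused"),
    (0.30, "feeling_bored"),
)


def _questionnaire_state(rate: float, rng: np.random.Generator) -> str:
    for cut, state in _STATE_CUTS:
        if rate >= cut:
            return state
    return "distracted" if rng.random() < 0.5 else "heavy_eyed"


def synth_session(
    spec: SyntheticSessionSpec,
    juror_id: str = "juror_1",
    attention_cfg: AttentionConfig | None = None,
) -> SyntheticSession:
    """Generate one complete juror session.

    Inattention is rendered physically — the head turned 55–80° away or the
    gaze parked off the screen window — so the attention column of the
    resulting frame table is produced by the landmark/gaze classifier, not
    copied from the latent state.  Attentive frames carry small pose jitter
    and spontaneous blinks (which the EAR-guarded classifier must not flag).
    """
    rng = np.random.default_rng(spec.seed)
    cfg = attention_cfg or AttentionConfig()
    schedule = build_schedule(spec.sounds, spec.segment_duration, spec.gap)
    timestamps = np.arange(0.0, schedule.t_end, 1.0 / spec.frame_rate)
    n = len(timestamps)

    attentive = synth_attention_states(
        n, spec.attention_rates, spec.attention_dwell_frames, rng
    )

    # pose and gaze
    yaw_deg = rng.normal(0.0, 4.0, n).clip(-12.0, 12.0)
    pitch_deg = rng.normal(0.0, 2.0, n).clip(-6.0, 6.0)
    gaze_x = rng.uniform(5.0, 20.0, n)
    inat = ~attentive
    head_turn = inat & (rng.random(n) < 0.5)
    # head turns stay within |yaw| <= 70 deg: beyond that the orthographic
    # template projection self-occludes and a real detector loses the face
    yaw_deg[head_turn] = rng.choice([-1.0, 1.0], int(head_turn.sum())) * rng.uniform(
        55.0, 70.0, int(head_turn.sum())
    )
    gaze_x[inat] = rng.uniform(27.0, 45.0, int(inat.sum()))

    # blinks: Poisson starts on attentive frames, fixed short duration
    openness = np.ones(n)
    p_blink = spec.blink_rate / spec.frame_rate
    starts = np.flatnonzero(attentive & (rng.random(n) < p_blink))
    for s in starts:
        openness[s : s + spec.blink_duration_frames] = 0.08

    landmarks = synth_landmark_stream(yaw_deg, pitch_deg, openness)
    attention, valid = classify_frames(landmarks, gaze_x, cfg)

    _, emo, target = synth_emotion_series(
        spec, schedule, timestamps=timestamps, inattentive=inat, rng=rng
    )

    frames = pd.DataFrame({"timestamp_s": timestamps})
    for j, name in enumerate(EMOTIONS):
        frames[f"{name}_pct"] = emo[:, j]
    frames["attention"] = attention
    frames = attach_metrics(frames)

    gaze = pd.DataFrame(
        {
            "timestamp_s": timestamps,
            "gaze_x_cm": gaze_x,
            "gaze_y_cm": rng.uniform(5.0, 25.0, n),
            "available": True,
        }
    )

    # answers follow the slope criterion with probability p_consistent
    slope_by_sound = dict(zip(spec.sounds, spec.slopes))
    answers = []
    for comp in schedule.comparisons:
        s1 = slope_by_sound[comp.sound_first]
        s2 = slope_by_sound[comp.sound_second]
        if s1 == s2:
            answers.append(AnswerRecord(comp.index))
            continue
        quality = "second" if s2 > s1 else "first"
        annoying = "first" if quality == "second" else "second"
        if rng.random() >= spec.p_consistent:
            annoying = "first" if rng.random() < 0.5 else "second"
        if rng.random() >= spec.p_consistent:
            quality = "first" if rng.random() < 0.5 else "second"
        answers.append(AnswerRecord(comp.index, q1_choice=annoying, q2_choice=quality))

    # self reports from realised latent per-period attention rates
    edges = np.linspace(0, n, 4).astype(int)
    responses = tuple(
        QuestionnaireResponse(
            period,
            _questionnaire_state(float(attentive[edges[k]: edges[k + 1]].mean()), rng),
        )
        for k, period in enumerate(PERIODS)
    )

    latent = pd.DataFrame(
        {"timestamp_s": timestamps, "attentive_true": attentive, "target_valence": target}
    )
    manifest = {
        "juror_id": juror_id,
        "generator": "jurysense.synthetic.synth_session",
        "spec": dataclasses.asdict(spec),
    }
    return SyntheticSession(
        juror_id=juror_id,
        spec=spec,
        schedule=schedule,
        frames=frames,
        landmarks=landmarks,
        gaze=gaze,
        answers=answers,
        responses=responses,
        latent=latent,
        manifest=manifest,
    )


def synth_cohort(
    n_jurors: int,
    spec_template: SyntheticSessionSpec | None = None,
    seed: int | None = None,
    heterogeneity: float = 1.0,
) -> list[SyntheticSession]:
    """Generate a cohort of heterogeneous juror sessions.

    Per-juror seeds are derived from the master seed; jurors vary mildly
    around the template in answer consistency (±0.05 s.d. scaled by
    ``heterogeneity``, clipped to [0.5, 1]) and in a common attention-rate
    factor (±0.05 s.d., rates capped at 1).  ``heterogeneity=0`` makes every
    juror share the template conditions exactly (seeds still differ).
    """
    if n_jurors < 1:
        raise ValueError("n_jurors must be >= 1")
    template = spec_template or SyntheticSessionSpec()
    master = np.random.default_rng(template.seed if seed is None else seed)
    sessions = []
    for j in range(n_jurors):
        juror_seed = int(master.integers(0, 2**31 - 1))
        jitter_p, jitter_f = master.normal(0.0, 0.05, 2)
        p_c = float(np.clip(template.p_consistent + heterogeneity * jitter_p, 0.5, 1.0))
        factor = float(np.clip(1.0 + heterogeneity * jitter_f, 0.8, 1.1))
        rates = tuple(min(1.0, r * factor) for r in template.attention_rates)
        spec = dataclasses.replace(
            template, seed=juror_seed, p_consistent=p_c, attention_rates=rates
        )
        sessions.append(synth_session(spec, juror_id=f"juror_{j + 1}"))
    return sessions
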