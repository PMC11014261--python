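"""Landmark-geometry and attention-classifier unit tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from jurysense.geometry import (
    AttentionConfig,
    DegenerateLandmarkError,
    GazeSample,
    HeadPoseFeatures,
    LandmarkSet,
    classify_frames,
    combined_attention,
    eye_aspect_ratio,
    face_attention,
    head_pose_features,
    landmark_distance,
    pitch_ratio,
    yaw_ratio,
)
from jurysense.synthetic import FacePoseModel, synth_landmarks


def features(yaw=1.0, pitch=1.0, ear=0.3):
    return HeadPoseFeatures(0, 0, 0, 0, 0, yaw=yaw, pitch=pitch, ear=ear)


def landmarks_with(pairs):
    """A landmark set with specified 1-based points, others on a unit grid."""
    pts = np.stack(
        [np.linspace(0, 67, 68), np.linspace(100, 167, 68)], axis=1
    ).astype(float)
    for idx, xy in pairs.items():
        pts[idx - 1] = xy
    return LandmarkSet(points=pts)


class TestLandmarkDistance:
    def test_identity_and_triangle(self):
        lm = landmarks_with({1: (0, 0), 2: (3, 4)})
        assert landmark_distance(lm, 1, 1) == 0.0
        assert landmark_distance(lm, 1, 2) == pytest.approx(5.0)
        assert landmark_distance(lm, 2, 1) == pytest.approx(5.0)

    def test_random_pairs_match_coordinate_oracle(self, rng):
        pts = rng.normal(size=(68, 2)) * 50
        lm = LandmarkSet(points=pts)
        for _ in range(100):
            i, j = rng.integers(1, 69, 2)
            expected = (
                (pts[i - 1, 0] - pts[j - 1, 0]) ** 2
                + (pts[i - 1, 1] - pts[j - 1, 1]) ** 2
            ) ** 0.5
            assert landmark_distance(lm, int(i), int(j)) == pytest.approx(expected)

    def test_index_out_of_range(self):
        lm = landmarks_with({})
        with pytest.raises(ValueError):
            landmark_distance(lm, 0, 5)
        with pytest.raises(ValueError):
            landmark_distance(lm, 1, 69)


class TestYawRatio:
    def test_symmetric_face_gives_one(self):
        lm = landmarks_with({2: (-10, 0), 31: (0, 0), 16: (10, 0)})
        assert yaw_ratio(lm) == pytest.approx(1.0)

    @pytest.mark.parametrize("a_x, b_x", [(-2, 10), (-10, 2)])
    def test_reciprocal_folding(self, a_x, b_x):
        # dist A and B of 2 and 10 in either order fold to 0.2
        lm = landmarks_with({2: (a_x, 0), 31: (0, 0), 16: (b_x, 0)})
        assert yaw_ratio(lm) == pytest.approx(0.2)

    def test_degenerate_raises(self):
        lm = landmarks_with({2: (0, 0), 31: (0, 0), 16: (10, 0)})
        with pytest.raises(DegenerateLandmarkError):
            yaw_ratio(lm)


class TestPitchRatio:
    def test_arithmetic(self):
        lm = landmarks_with(
            {28: (0, 0), 31: (0, 10), 37: (0, 50), 40: (10, 50), 43: (20, 50), 46: (21, 50)}
        )
        assert pitch_ratio(lm) == pytest.approx(1.0)

    def test_fallback_to_right_eye(self):
        lm = landmarks_with(
            {28: (0, 0), 31: (0, 12), 37: (5, 50), 40: (5, 50), 43: (20, 50), 46: (22, 50)}
        )
        assert pitch_ratio(lm) == pytest.approx(6.0)

    def test_scale_invariance(self):
        lm = synth_landmarks(FacePoseModel(yaw_angle=20, pitch_angle=5))
        lm2 = LandmarkSet(points=lm.points * 3.7)
        assert pitch_ratio(lm2) == pytest.approx(pitch_ratio(lm))

    def test_both_eyes_degenerate(self):
        lm = landmarks_with(
            {28: (0, 0), 31: (0, 12), 37: (5, 50), 40: (5, 50), 43: (20, 50), 46: (20, 50)}
        )
        with pytest.raises(DegenerateLandmarkError):
            pitch_ratio(lm)


class TestEyeAspectRatio:
    def test_hexad_formula(self):
        hexad = {37: (0, 0), 38: (1, 1), 39: (3, 1), 40: (4, 0), 41: (3, -1), 42: (1, -1)}
        mirror = {43: (10, 0), 44: (11, 1), 45: (13, 1), 46: (14, 0), 47: (13, -1), 48: (11, -1)}
        lm = landmarks_with({**hexad, **mirror})
        assert eye_aspect_ratio(lm) == pytest.approx(0.5)

    def test_closed_eye_is_zero(self):
        lm = synth_landmarks(FacePoseModel(eye_openness=0.0))
        assert eye_aspect_ratio(lm) == pytest.approx(0.0)

    def test_scale_invariance(self):
        lm = synth_landmarks(FacePoseModel())
        scaled = LandmarkSet(points=lm.points * 10.0)
        assert eye_aspect_ratio(scaled) == pytest.approx(eye_aspect_ratio(lm))


class TestFaceAttention:
    def test_yaw_gate(self):
        assert not face_attention(features(yaw=0.2, pitch=1, ear=0.3))
        assert not face_attention(features(yaw=0.2, pitch=9, ear=0.05))

    def test_pitch_ear_gate_both_modes(self):
        guarded = AttentionConfig(pitch_gate_mode="ear_guarded")
        literal = AttentionConfig(pitch_gate_mode="literal")
        f = features(yaw=0.9, pitch=6, ear=0.05)
        assert not face_attention(f, guarded)
        assert not face_attention(f, literal)
        # high pitch with open eyes: only the literal mode flags it
        f2 = features(yaw=0.9, pitch=6, ear=0.3)
        assert face_attention(f2, guarded)
        assert not face_attention(f2, literal)

    def test_boundary_semantics(self):
        guarded = AttentionConfig()
        # yaw exactly at threshold counts attentive ("less than" flags)
        assert face_attention(features(yaw=0.4), guarded)
        # pitch exactly at threshold does not fire the guarded gate
        assert face_attention(features(yaw=0.9, pitch=5.0, ear=0.05), guarded)


class TestCombinedAttention:
    @pytest.mark.parametrize(
        "face, gx, expected",
        [(True, 12.0, True), (True, 30.0, False), (False, 12.0, False),
         (True, 1.0, False), (True, 25.0, False)],
    )
    def test_window(self, face, gx, expected):
        assert combined_attention(face, GazeSample(gx, 10.0)) is expected

    def test_missing_gaze_policies(self):
        missing = GazeSample(available=False)
        assert combined_attention(True, missing, AttentionConfig()) is True
        strict = AttentionConfig(gaze_missing_policy="inattentive")
        assert combined_attention(True, missing, strict) is False

    def test_never_true_without_face_attention(self):
        for gx in np.linspace(-5, 50, 23):
            assert combined_attention(False, GazeSample(float(gx), 5.0)) is False


class TestSimilarityInvariance:
    @given(
        st.floats(min_value=-np.pi, max_value=np.pi),
        st.floats(min_value=0.2, max_value=5.0),
        st.floats(min_value=-500, max_value=500),
        st.floats(min_value=-500, max_value=500),
    )
    def test_ratios_invariant(self, angle, scale, tx, ty):
        lm = synth_landmarks(FacePoseModel(yaw_angle=25, pitch_angle=8))
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = LandmarkSet(points=lm.points @ rot.T * scale + [tx, ty])
        assert yaw_ratio(moved) == pytest.approx(yaw_ratio(lm), rel=1e-9)
        assert pitch_ratio(moved) == pytest.approx(pitch_ratio(lm), rel=1e-9)
        assert eye_aspect_ratio(moved) == pytest.approx(eye_aspect_ratio(lm), rel=1e-9)

    def test_mirror_leaves_yaw_unchanged(self, rng):
        for _ in range(20):
            lm = synth_landmarks(
                FacePoseModel(yaw_angle=float(rng.uniform(-50, 50)))
            )
            mirrored = LandmarkSet(points=lm.points * [-1.0, 1.0] + [640.0, 0.0])
            assert yaw_ratio(mirrored) == pytest.approx(yaw_ratio(lm), rel=1e-12)


class TestClassifyFrames:
    def test_matches_scalar_path(self, rng):
        poses = [
            FacePoseModel(
                yaw_angle=float(rng.uniform(-70, 70)),
                pitch_angle=float(rng.uniform(-20, 20)),
                eye_openness=float(rng.uniform(0.05, 1.0)),
            )
            for _ in range(60)
        ]
        lms = np.stack([synth_landmarks(p).points for p in poses])
        gx = rng.uniform(-5, 40, 60)
        batch, valid = classify_frames(lms, gx)
        assert valid.all()
        for k, p in enumerate(poses):
            f = head_pose_features(synth_landmarks(p))
            expected = combined_attention(face_attention(f), GazeSample(gx[k], 10.0))
            assert batch[k] == expected

    def test_degenerate_frames_marked_invalid(self):
        lms = np.zeros((2, 68, 2))
        lms[1] = synth_landmarks(FacePoseModel()).points
        attn, valid = classify_frames(lms)
        assert not valid[0] and not attn[0]
        assert valid[1] and attn[1]
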