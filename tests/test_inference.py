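"""Trend fitting, choice simulation and reliability-correlation tests."""

import numpy as np
import pandas as pd
import pytest

from jurysense.inference import (
    JurorReliability,
    correlation_threshold_curve,
    fit_segment_trend,
    juror_answer_correlation,
    simulate_choices,
)
from jurysense.session import (
    AnswerRecord,
    Comparison,
    ComparisonSegment,
    InsufficientDataError,
)


def _frames(t, v, attention=True):
    return pd.DataFrame({"timestamp_s": t, "valence": v, "attention": attention})


def make_segment(slope_first, slope_second, n=20, answers=None, noise=0.0,
                 rng=None, attention=True):
    t = np.linspace(0.0, 10.0, n)
    v1 = slope_first * t
    v2 = slope_second * t
    if noise and rng is not None:
        v1 = v1 + rng.normal(0, noise, n)
        v2 = v2 + rng.normal(0, noise, n)
    comp = Comparison(0, "a", "b", 0, 10, 10, 20)
    # both sub-segments share the timestamp grid so equal injected slopes
    # produce bit-identical fits (exact ties)
    return ComparisonSegment(
        comparison=comp,
        frames_first=_frames(t, v1, attention),
        frames_second=_frames(t, v2, attention),
        answers=answers or AnswerRecord(0),
    )


class TestFitSegmentTrend:
    def test_noiseless_line(self):
        t = np.linspace(0, 10, 30)
        fit = fit_segment_trend(t, 2.0 * t + 1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.rho == pytest.approx(1.0)

    def test_constant_valence_convention(self):
        fit = fit_segment_trend(np.arange(10.0), np.full(10, 7.0))
        assert (fit.slope, fit.r_squared, fit.rho) == (0.0, 0.0, 0.0)
        assert fit.intercept == pytest.approx(7.0)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_segment_trend(np.array([1.0]), np.array([2.0]))
        with pytest.raises(InsufficientDataError):
            fit_segment_trend(np.array([1.0, 1.0]), np.array([2.0, 3.0]))

    def test_matches_normal_equations_oracle(self, rng):
        """OLS, R² and ρ agree with closed-form normal equations to 1e-9."""
        for _ in range(200):
            n = int(rng.integers(5, 60))
            t = np.sort(rng.uniform(0, 30, n))
            v = rng.normal(0, 5, n) + rng.uniform(-3, 3) * t
            fit = fit_segment_trend(t, v)
            sxx = n * (t**2).sum() - t.sum() ** 2
            slope = (n * (t * v).sum() - t.sum() * v.sum()) / sxx
            intercept = v.mean() - slope * t.mean()
            ss_res = ((v - intercept - slope * t) ** 2).sum()
            ss_tot = ((v - v.mean()) ** 2).sum()
            rho = ((t - t.mean()) * (v - v.mean())).sum() / np.sqrt(
                ((t - t.mean()) ** 2).sum() * ((v - v.mean()) ** 2).sum()
            )
            assert fit.slope == pytest.approx(slope, abs=1e-9, rel=1e-9)
            assert fit.intercept == pytest.approx(intercept, abs=1e-9, rel=1e-9)
            assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot, abs=1e-9)
            assert fit.rho == pytest.approx(rho, abs=1e-9)

    def test_rho_squared_equals_r_squared_and_n_convention_cancels(self, rng):
        for _ in range(50):
            t = np.sort(rng.uniform(0, 10, 25))
            v = rng.normal(0, 2, 25) + t
            fit = fit_segment_trend(t, v)
            assert fit.rho**2 == pytest.approx(fit.r_squared, abs=1e-9)
            # population (N) vs sample (N-1) normalised correlation coincide
            rho_n = np.mean((t - t.mean()) * (v - v.mean())) / (t.std() * v.std())
            assert fit.rho == pytest.approx(rho_n, abs=1e-12)
            assert np.sign(fit.rho) == np.sign(fit.slope)


class TestSimulateChoices:
    @pytest.mark.parametrize(
        "s1, s2, q1, q2",
        [
            (1.0, -1.0, "second", "first"),
            (-1.0, 1.0, "first", "second"),
            (2.0, 0.5, "second", "first"),   # same-sign pair: order by slope
            (1.0, 1.0, "abstain", "abstain"),
        ],
    )
    def test_relative_trend_criterion(self, s1, s2, q1, q2):
        choice = simulate_choices(make_segment(s1, s2))
        assert (choice.predicted_q1, choice.predicted_q2) == (q1, q2)

    def test_strict_mode_abstains_on_same_sign(self):
        seg = make_segment(2.0, 0.5)
        choice = simulate_choices(seg, require_opposite_signs=True)
        assert choice.predicted_q1 == choice.predicted_q2 == "abstain"

    def test_min_frames_abstention(self):
        seg = make_segment(1.0, -1.0, n=3)
        choice = simulate_choices(seg, min_frames=5)
        assert choice.predicted_q1 == "abstain"

    def test_tie_epsilon(self):
        seg = make_segment(1.0, 1.05)
        assert simulate_choices(seg, slope_tie_epsilon=0.1).predicted_q2 == "abstain"
        assert simulate_choices(seg, slope_tie_epsilon=0.01).predicted_q2 == "second"

    def test_predictions_never_coincide(self, rng):
        for _ in range(50):
            s1, s2 = rng.normal(0, 2, 2)
            choice = simulate_choices(make_segment(float(s1), float(s2)))
            if choice.predicted_q1 != "abstain":
                assert choice.predicted_q1 != choice.predicted_q2


def _spearman_oracle(x, y):
    """Independent midrank-then-Pearson implementation."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestJurorAnswerCorrelation:
    def _segments(self, slopes, answers_fn, rng=None, noise=0.0):
        segs = []
        for k, (s1, s2) in enumerate(slopes):
            q1, q2 = answers_fn(s1, s2)
            seg = make_segment(s1, s2, answers=AnswerRecord(0, q1, q2),
                               noise=noise, rng=rng)
            seg.comparison = Comparison(k, "a", "b", 0, 10, 10, 20)
            segs.append(seg)
        return segs

    def test_perfect_concordance(self):
        slopes = [(float(a), float(b)) for a in (-2, -1, 0.5, 2)
                  for b in (-1.5, 0.25, 1.0) if a != b]
        segs = self._segments(
            slopes,
            lambda s1, s2: (("first", "second") if s2 > s1 else ("second", "first")),
        )
        for q in ("q1", "q2"):
            rho, n = juror_answer_correlation(segs, q)
            assert rho == pytest.approx(1.0)
            assert n == len(slopes)

    def test_perfect_discordance(self):
        slopes = [(-1.0, 1.0), (2.0, -2.0), (0.5, 1.5), (3.0, 1.0), (-2.0, -0.5)]
        segs = self._segments(
            slopes,
            lambda s1, s2: (("second", "first") if s2 > s1 else ("first", "second")),
        )
        rho, _ = juror_answer_correlation(segs, "q2")
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_oracle_on_random_answers(self, rng):
        slopes = [tuple(rng.normal(0, 2, 2)) for _ in range(30)]
        segs = self._segments(
            slopes,
            lambda s1, s2: (
                ("first", "second") if rng.random() < 0.5 else ("second", "first")
            ),
        )
        for encoding in ("sign", "difference"):
            rho, n = juror_answer_correlation(segs, "q2", trend_encoding=encoding)
            x = []
            y = []
            for seg in segs:
                d = (fit_segment_trend(seg.frames_second).slope
                     - fit_segment_trend(seg.frames_first).slope)
                x.append(np.sign(d) if encoding == "sign" else d)
                y.append(1.0 if seg.answers.q2_choice == "second" else -1.0)
            assert rho == pytest.approx(_spearman_oracle(x, y), abs=1e-9)

    def test_missing_answers_dropped(self):
        segs = self._segments(
            [(-1.0, 1.0), (1.0, -1.0), (-2.0, 2.0), (2.0, -2.0)],
            lambda s1, s2: (("first", "second") if s2 > s1 else ("second", "first")),
        )
        segs[0].answers = AnswerRecord(0, "none", "none")
        rho, n = juror_answer_correlation(segs, "q2")
        assert n == 3
        assert rho == pytest.approx(1.0)

    def test_insufficient_comparisons_flagged(self):
        segs = self._segments(
            [(-1.0, 1.0), (1.0, -1.0)],
            lambda s1, s2: (("first", "second") if s2 > s1 else ("second", "first")),
        )
        rho, n = juror_answer_correlation(segs, "q2")
        assert np.isnan(rho) and n == 2

    def test_attention_filter_drops_sparse_segments(self):
        segs = self._segments(
            [(-1.0, 1.0), (1.0, -1.0), (-2.0, 2.0), (2.0, -2.0)],
            lambda s1, s2: (("first", "second") if s2 > s1 else ("second", "first")),
        )
        # one comparison has almost no attentive frames in its first segment
        attn = np.zeros(len(segs[0].frames_first), dtype=bool)
        attn[:2] = True
        segs[0].frames_first = segs[0].frames_first.assign(attention=attn)
        rho_f, n_f = juror_answer_correlation(segs, "q2", attention_filter=True)
        assert n_f == 3
        assert rho_f == pytest.approx(1.0)


class TestThresholdCurve:
    def _juror(self, jid, rho_all, rho_filtered):
        return JurorReliability(jid, rho_all, rho_all, rho_filtered, rho_filtered, 42, 40)

    def test_example_counts(self):
        cohort = [self._juror("j1", 0.5, 0.9)]
        curve = correlation_threshold_curve(cohort, [0.7])
        assert curve.loc[0, "n_all"] == 0
        assert curve.loc[0, "n_filtered"] == 1

    def test_floor_threshold_counts_nonnegative_rho(self):
        cohort = [self._juror(f"j{i}", r, r) for i, r in
                  enumerate([-0.5, 0.0, 0.3, 0.9])]
        curve = correlation_threshold_curve(cohort, [0.0])
        assert curve.loc[0, "n_all"] == 3

    def test_monotone_and_matches_counting_oracle(self, rng):
        cohort = [
            self._juror(f"j{i}", float(rng.uniform(-1, 1)), float(rng.uniform(-1, 1)))
            for i in range(25)
        ]
        taus = np.linspace(0, 1, 21)
        curve = correlation_threshold_curve(cohort, taus)
        for col, attr in (("n_all", "rho_q2_all"), ("n_filtered", "rho_q2_filtered")):
            counts = curve[col].to_numpy()
            assert (np.diff(counts) <= 0).all()
            for tau, c in zip(taus, counts):
                assert c == sum(getattr(j, attr) >= tau for j in cohort)

    def test_nan_rho_never_counts(self):
        cohort = [self._juror("j1", float("nan"), 0.9)]
        curve = correlation_threshold_curve(cohort, [0.0])
        assert curve.loc[0, "n_all"] == 0
        assert curve.loc[0, "n_filtered"] == 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            correlation_threshold_curve([], [0.5])
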