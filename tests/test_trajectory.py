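import numpy as np
import pytest

from crisischat.synthetic import EmotionModel, GeneratorConfig, generate_corpus
from crisischat.trajectory import (
    aggregate_trajectories,
    eligible_visits,
    interpolate_trajectory,
    percent_change,
    trajectory_curves,
)
from crisischat.transcript import ChatSession, Corpus, Message, UserVisit


def _session_with_scores(scores, sid="s1", emotion="despair", user="s1_u0"):
    msgs = []
    for i, sc in enumerate(scores):
        emo = {emotion: sc} if sc is not None else {}
        msgs.append(Message(sid, user, "participant", 10.0 * (i + 1), i, "txt", emo))
    return ChatSession(session_id=sid, month=1, messages=msgs, topic="anxiety")


def _corpus_of(sessions, group="non_exposed_non_si"):
    visits = [UserVisit(s.messages[0].user_id, s.session_id, group) for s in sessions]
    return Corpus(sessions=list(sessions), visits=visits)


class TestInterpolation:
    def test_linear_midpoint(self):
        s = _session_with_scores([6, 2])
        curve = interpolate_trajectory(s, "s1_u0", "despair", grid_points=3)
        assert curve.tolist() == [6.0, 4.0, 2.0]

    def test_constant_scores_give_flat_curve(self):
        s = _session_with_scores([5, 5, 5, 5])
        curve = interpolate_trajectory(s, "s1_u0", "despair", grid_points=11)
        assert np.allclose(curve, 5.0)

    def test_three_knots_on_five_point_grid(self):
        s = _session_with_scores([9, 3, 6])
        curve = interpolate_trajectory(s, "s1_u0", "despair", grid_points=5)
        assert curve.tolist() == [9.0, 6.0, 3.0, 4.5, 6.0]

    def test_exact_on_knots_and_bounded_by_them(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            m = int(rng.integers(2, 9))
            scores = rng.integers(1, 11, size=m).tolist()
            s = _session_with_scores(scores)
            curve = interpolate_trajectory(s, "s1_u0", "despair", grid_points=m)
            assert curve.tolist() == [float(x) for x in scores]  # grid == knots
            fine = interpolate_trajectory(s, "s1_u0", "despair", grid_points=101)
            assert fine.min() >= min(scores) and fine.max() <= max(scores)

    def test_monotone_knots_give_monotone_curve(self):
        s = _session_with_scores([9, 7, 4, 2])
        curve = interpolate_trajectory(s, "s1_u0", "despair", grid_points=41)
        assert (np.diff(curve) <= 1e-12).all()

    def test_absent_scores_are_skipped_as_knots(self):
        s = _session_with_scores([6, None, 2])
        curve = interpolate_trajectory(s, "s1_u0", "despair", grid_points=3)
        assert curve.tolist() == [6.0, 4.0, 2.0]

    def test_fewer_than_two_scores_raises_and_is_skipped(self):
        s = _session_with_scores([6, None, None])
        with pytest.raises(ValueError, match="need >= 2"):
            interpolate_trajectory(s, "s1_u0", "despair")
        curves, kept = trajectory_curves(_corpus_of([s]), [("s1", "s1_u0")], "despair")
        assert curves == [] and kept == []


class TestEligibility:
    def test_threshold_reached_within_first_three_messages(self):
        s = _session_with_scores([3, None, 5, 2])
        corpus = _corpus_of([s])
        assert eligible_visits(corpus, "despair", group="non_exposed_non_si") == [("s1", "s1_u0")]

    def test_all_below_threshold_is_ineligible(self):
        s = _session_with_scores([4, 4, 4])
        assert eligible_visits(_corpus_of([s]), "despair", group="non_exposed_non_si") == []

    def test_fourth_message_score_does_not_qualify(self):
        s = _session_with_scores([4, 4, 4, 9])
        assert eligible_visits(_corpus_of([s]), "despair", group="non_exposed_non_si") == []

    def test_active_si_always_excluded(self):
        s = _session_with_scores([9, 9, 9])
        s.si_label, s.si_discloser = "active", "s1_u0"
        corpus = _corpus_of([s], group="active_si")
        assert eligible_visits(corpus, "despair", group="active_si") == []

    def test_unknown_emotion_raises(self):
        with pytest.raises(ValueError, match="unknown emotion"):
            eligible_visits(_corpus_of([_session_with_scores([5])]), "anger",
                            group="non_exposed_non_si")

    def test_gate_emotions_can_differ_from_analyzed_emotion(self):
        s = _session_with_scores([7, 7, 7], emotion="despair")
        for m in s.messages:
            m.emotions["optimism"] = 2
        corpus = _corpus_of([s])
        assert eligible_visits(
            corpus, "optimism", group="non_exposed_non_si", threshold_emotions=["despair"]
        ) == [("s1", "s1_u0")]
        assert eligible_visits(corpus, "optimism", group="non_exposed_non_si") == []


class TestAggregation:
    def test_single_curve_aggregates_to_itself(self):
        c = np.array([4.0, 5.0, 6.0])
        agg = aggregate_trajectories([c], "despair")
        assert agg.values.tolist() == c.tolist() and agg.n == 1

    def test_two_flat_curves_average(self):
        agg = aggregate_trajectories([np.full(5, 4.0), np.full(5, 6.0)], "despair")
        assert np.allclose(agg.values, 5.0)
        assert np.allclose(agg.sd, np.std([4.0, 6.0], ddof=1))

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="grid mismatch"):
            aggregate_trajectories([np.zeros(5), np.zeros(7)])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        curves = [rng.uniform(1, 10, size=11) for _ in range(6)]
        a = aggregate_trajectories(curves, "despair")
        b = aggregate_trajectories(curves[::-1], "despair")
        assert np.allclose(a.values, b.values) and np.allclose(a.sd, b.sd)


class TestPercentChange:
    def test_negative_emotion_reduction(self):
        agg = aggregate_trajectories([np.linspace(6.74, 3.74, 5)], "depression")
        assert percent_change(agg) == pytest.approx((6.74 - 3.74) / 6.74 * 100)  # 44.5%

    def test_flat_curve_is_zero(self):
        agg = aggregate_trajectories([np.full(5, 4.2)], "despair")
        assert percent_change(agg) == 0.0

    def test_optimism_increase(self):
        agg = aggregate_trajectories([np.linspace(2.0, 3.0, 5)], "optimism")
        assert percent_change(agg) == pytest.approx(50.0)

    def test_zero_begin_raises(self):
        curve = aggregate_trajectories([np.linspace(1.0, 2.0, 3)], "despair")
        curve.values[0] = 0.0
        with pytest.raises(ValueError):
            percent_change(curve)


class TestNoiselessRecovery:
    def test_generated_noiseless_curves_recover_configured_levels(self):
        """With zero noise and no absent scores, aggregated passive-SI
        depression trajectories start and end at the configured means."""
        em = EmotionModel(noise_sd=0.0, p_absent=0.0)
        cfg = GeneratorConfig(
            n_sessions=1500, seed=31, prevalence_passive=0.12, prevalence_active=0.0,
            emotion_model=em,
        )
        corpus = generate_corpus(cfg)
        pairs = [
            (s.session_id, s.si_discloser)
            for s in corpus.sessions
            if s.si_label == "passive"
        ]
        curves, _ = trajectory_curves(corpus, pairs, "depression")
        agg = aggregate_trajectories(curves, "depression")
        se_b = agg.sd[0] / np.sqrt(agg.n)
        se_e = agg.sd[-1] / np.sqrt(agg.n)
        assert abs(agg.begin - 6.74) < 3 * se_b
        assert abs(agg.end - 3.74) < 3 * se_e
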