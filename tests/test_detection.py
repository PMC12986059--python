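import pytest

from crisischat.detection import (
    ConfusionCounts,
    PrevalenceSummary,
    confusion_counts,
    detection_metrics,
    flag_latency_stats,
    prevalence_summary,
    referral_latency_stats,
)
from crisischat.transcript import ChatSession, Corpus, FlagEvent, Message, UserVisit


def _session(sid, si="none", flags=(), user=None):
    user = user or f"{sid}_u0"
    msgs = [
        Message(sid, user, "participant", 10.0 * (i + 1), i, "hi", {}) for i in range(3)
    ]
    return ChatSession(
        session_id=sid,
        month=1,
        messages=msgs,
        si_label=si,
        si_discloser=user if si != "none" else None,
        topic="anxiety",
        flags=list(flags),
    )


def _corpus(sessions):
    visits = []
    for s in sessions:
        group = {"none": "non_exposed_non_si", "passive": "passive_si", "active": "active_si"}[
            s.si_label
        ]
        visits.append(UserVisit(f"{s.session_id}_u0", s.session_id, group))
    return Corpus(sessions=list(sessions), visits=visits)


class TestConfusion:
    def test_one_session_of_each_kind(self):
        ai = FlagEvent("ai", "crisis_flag", 5.0)
        mod = FlagEvent("moderator", "protocol_question", 8.0)
        corpus = _corpus(
            [
                _session("both", "passive", [ai, mod]),
                _session("aionly", flags=[ai]),
                _session("modonly", "passive", [mod]),
                _session("neither"),
            ]
        )
        c = confusion_counts(corpus)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_no_disagreement_when_flags_coincide(self):
        both = [FlagEvent("ai", "crisis_flag", 5.0), FlagEvent("moderator", "protocol_question", 8.0)]
        corpus = _corpus([_session("a", "passive", both), _session("b"), _session("c")])
        c = confusion_counts(corpus)
        assert c.fp == 0 and c.fn == 0

    def test_ai_flag_after_protocol_still_counts_as_agreement(self):
        flags = [FlagEvent("moderator", "protocol_question", 5.0), FlagEvent("ai", "crisis_flag", 50.0)]
        c = confusion_counts(_corpus([_session("a", "passive", flags)]))
        assert c.tp == 1

    def test_sensitivity_recovered_on_generated_corpus(self, flag_corpus):
        c = confusion_counts(flag_corpus)
        sens = c.tp / (c.tp + c.fn)
        se = (0.8751 * (1 - 0.8751) / (c.tp + c.fn)) ** 0.5
        assert abs(sens - 0.8751) < 3 * se


class TestMetrics:
    def test_reported_confusion_counts_give_reported_percentages(self):
        m = detection_metrics(ConfusionCounts(tp=12602, fp=14735, fn=1799, tn=140666))
        assert m.as_percentages() == {
            "sensitivity": 87.51,
            "specificity": 90.52,
            "precision": 46.10,
            "npv": 98.74,
            "accuracy": 90.26,
        }

    def test_perfect_agreement_is_all_hundred(self):
        m = detection_metrics(ConfusionCounts(tp=7, fp=0, fn=0, tn=13))
        assert all(v == 100.0 for v in m.as_percentages().values())

    def test_hand_computed_small_example(self):
        m = detection_metrics(ConfusionCounts(tp=8, fp=2, fn=2, tn=88)).as_percentages()
        assert m["sensitivity"] == 80.00
        assert m["precision"] == 80.00
        assert m["accuracy"] == 96.00

    def test_zero_denominator_is_flagged_not_zero(self):
        m = detection_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=9))
        assert m.sensitivity is None and m.precision is None
        assert set(m.undefined) == {"sensitivity", "precision"}
        assert m.specificity == 1.0

    def test_all_zero_counts_raise(self):
        with pytest.raises(ValueError):
            detection_metrics(ConfusionCounts(0, 0, 0, 0))

    @pytest.mark.parametrize("k", [2, 7])
    def test_metrics_invariant_to_scaling_counts(self, k):
        base = ConfusionCounts(tp=8, fp=2, fn=2, tn=88)
        scaled = ConfusionCounts(tp=8 * k, fp=2 * k, fn=2 * k, tn=88 * k)
        a, b = detection_metrics(base), detection_metrics(scaled)
        for name in ("sensitivity", "specificity", "precision", "npv", "accuracy"):
            assert getattr(a, name) == pytest.approx(getattr(b, name))


class TestFlagLatency:
    def _with_diffs(self, diffs, si="active"):
        sessions = []
        for i, d in enumerate(diffs):
            t1 = 100.0
            flags = [
                FlagEvent("ai", "crisis_flag", t1),
                FlagEvent("moderator", "protocol_question", t1 + d),
            ]
            sessions.append(_session(f"s{i}", si, flags))
        return _corpus(sessions)

    def test_forced_arithmetic_example(self):
        stats = flag_latency_stats(self._with_diffs([10.0, 20.0, -6.0]), "active")
        assert stats.mean == pytest.approx(8.0)
        assert stats.p_ai_first == pytest.approx(2 / 3)
        assert stats.follow_up_mean == pytest.approx(15.0)

    def test_simultaneous_flags(self):
        stats = flag_latency_stats(self._with_diffs([0.0, 0.0], si="passive"), "passive")
        assert stats.mean == 0.0 and stats.sd == 0.0 and stats.p_ai_first == 0.0

    def test_empty_result_when_no_qualifying_sessions(self):
        stats = flag_latency_stats(_corpus([_session("a")]), "active")
        assert stats.empty and stats.mean is None

    def test_ai_first_share_recovered_on_generated_corpus(self, flag_corpus):
        stats = flag_latency_stats(flag_corpus, "active")
        se = (0.8126 * (1 - 0.8126) / stats.n) ** 0.5
        assert abs(stats.p_ai_first - 0.8126) < 3 * se


class TestReferralLatency:
    def _with_delays(self, delays):
        sessions = []
        for i, d in enumerate(delays):
            flags = [
                FlagEvent("ai", "crisis_flag", 50.0),
                FlagEvent("moderator", "protocol_question", 80.0),
                FlagEvent("moderator", "referral", 80.0 + d),
            ]
            sessions.append(_session(f"s{i}", "active", flags))
        return _corpus(sessions)

    def test_two_session_mean(self):
        stats = referral_latency_stats(self._with_delays([100.0, 300.0]))
        assert stats.mean == pytest.approx(200.0)

    def test_referral_at_question_time_is_zero_delay(self):
        assert referral_latency_stats(self._with_delays([0.0])).mean == 0.0

    def test_delay_measured_from_last_question(self):
        flags = [
            FlagEvent("moderator", "protocol_question", 80.0),
            FlagEvent("moderator", "safety_question", 120.0),
            FlagEvent("moderator", "referral", 150.0),
        ]
        stats = referral_latency_stats(_corpus([_session("s0", "active", flags)]))
        assert stats.mean == pytest.approx(30.0)

    def test_empty_without_active_sessions(self):
        assert referral_latency_stats(_corpus([_session("a")])).empty


class TestPrevalence:
    def test_reported_counts_reproduce_reported_rates(self):
        prev = PrevalenceSummary.from_counts(
            passive=8929, active=5472, total_visits=449_946, exposed_visits=22_346
        )
        assert round(prev.passive_rate_visits * 100, 2) == 1.98
        assert prev.active_rate_visits == 5472 / 449_946  # exact fraction exposed
        assert round(prev.exposure_rate * 100, 2) == 4.97
        assert prev.ratio_label() == "1.6:1"

    def test_corpus_without_si_has_zero_rates_and_undefined_ratio(self):
        prev = prevalence_summary(_corpus([_session("a"), _session("b")]))
        assert prev.passive_rate_visits == 0.0
        assert prev.passive_active_ratio is None and prev.ratio_label() is None

    def test_monthly_counts_sum_to_class_totals(self, si_corpus):
        prev = prevalence_summary(si_corpus)
        assert sum(prev.monthly_passive.values()) == prev.passive_sessions
        assert sum(prev.monthly_active.values()) == prev.active_sessions
        assert sum(prev.monthly_sessions.values()) == prev.n_sessions

    def test_exposure_counts_disclosers_and_peers(self):
        ai = FlagEvent("ai", "crisis_flag", 5.0)
        mod = FlagEvent("moderator", "protocol_question", 8.0)
        s = _session("s0", "passive", [ai, mod])
        corpus = _corpus([s, _session("s1")])
        corpus.visits.append(UserVisit("s0_u1", "s0", "exposed_non_si"))
        prev = prevalence_summary(corpus)
        assert prev.exposed_visits == 2  # discloser + peer
        assert prev.n_visits == 3
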