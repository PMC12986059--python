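"""Hybrid crisis-detection evaluation.

The moderator's protocol initiation is the benchmark truth: a session where
both the AI and the moderator flagged is a true positive, AI-only is a false
positive, moderator-only a false negative, and neither a true negative.
From the confusion counts the five reported metrics follow (sensitivity,
specificity, precision, NPV, accuracy); flag latency is the signed
difference T2 - T1 between the moderator protocol question and the AI
crisis flag, and referral timeliness is the delay from the moderator's last
crisis-determination question to delivery of crisis resources.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .transcript import Corpus

_METRICS = ("sensitivity", "specificity", "precision", "npv", "accuracy")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DetectionMetrics:
    """Exact fractions in [0, 1]; a metric whose denominator is zero is None
    and listed in ``undefined`` rather than silently reported as 0."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]
    undefined: tuple[str, ...] = ()

    def as_percentages(self, decimals: int = 2) -> dict[str, Optional[float]]:
        """Percent formatting with round-half-even, as conventionally printed."""
        out = {}
        for name in _METRICS:
            v = getattr(self, name)
            out[name] = None if v is None else round(v * 100.0, decimals)
        return out


def confusion_counts(corpus: Corpus) -> ConfusionCounts:
    """Per-session agreement of the AI crisis flag with the moderator
    protocol initiation.  Depends only on flag events, never on message
    content; an AI flag raised after the moderator's question still counts
    as agreement (order affects only the latency statistics)."""
    tp = fp = fn = tn = 0
    for s in corpus.sessions:
        ai = s.first_flag("ai", "crisis_flag") is not None
        mod = s.first_flag("moderator", "protocol_question") is not None
        if ai and mod:
            tp += 1
        elif ai:
            fp += 1
        elif mod:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def detection_metrics(counts: ConfusionCounts) -> DetectionMetrics:
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    values = {
        "sensitivity": ratio(counts.tp, counts.tp + counts.fn),
        "specificity": ratio(counts.tn, counts.tn + counts.fp),
        "precision": ratio(counts.tp, counts.tp + counts.fp),
        "npv": ratio(counts.tn, counts.tn + counts.fn),
        "accuracy": ratio(counts.tp + counts.tn, counts.total),
    }
    undefined = tuple(k for k, v in values.items() if v is None)
    return DetectionMetrics(undefined=undefined, **values)


@dataclass(frozen=True)
class LatencyStats:
    """Statistics of flag or referral latencies, in seconds.

    For flag latency the primary sample is the signed difference T2 - T1
    over sessions with both flags (negative = moderator first).  The
    ``follow_up_*`` fields summarize the AI-first subset only (T2 - T1 > 0),
    i.e. how long after the AI alert the moderator initiated the protocol.
    """

    n: int
    mean: Optional[float]
    sd: Optional[float]
    p_ai_first: Optional[float] = None
    follow_up_n: int = 0
    follow_up_mean: Optional[float] = None
    follow_up_sd: Optional[float] = None

    @property
    def empty(self) -> bool:
        return self.n == 0


def _stats(x: np.ndarray) -> tuple[Optional[float], Optional[float]]:
    if x.size == 0:
        return None, None
    return float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0


def flag_latency_stats(corpus: Corpus, si_class: str) -> LatencyStats:
    """T2 - T1 over sessions of ``si_class`` having both an AI crisis flag
    (T1) and a moderator protocol question (T2, first one)."""
    if si_class not in ("passive", "active"):
        raise ValueError(f"si_class must be 'passive' or 'active', got {si_class!r}")
    diffs = []
    for s in corpus.sessions:
        if s.si_label != si_class:
            continue
        ai = s.first_flag("ai", "crisis_flag")
        mod = s.first_flag("moderator", "protocol_question")
        if ai is None or mod is None:
            continue
        diffs.append(mod.t - ai.t)
    arr = np.asarray(diffs)
    if arr.size == 0:
        return LatencyStats(n=0, mean=None, sd=None, p_ai_first=None)
    mean, sd = _stats(arr)
    pos = arr[arr > 0]
    fu_mean, fu_sd = _stats(pos)
    return LatencyStats(
        n=int(arr.size),
        mean=mean,
        sd=sd,
        p_ai_first=float((arr > 0).mean()),
        follow_up_n=int(pos.size),
        follow_up_mean=fu_mean,
        follow_up_sd=fu_sd,
    )


def referral_latency_stats(corpus: Corpus) -> LatencyStats:
    """Referral time minus the moderator's last crisis-determination
    question (protocol or safety), over active-SI sessions with both."""
    delays = []
    for s in corpus.sessions:
        if s.si_label != "active":
            continue
        ref = s.last_flag("moderator", "referral")
        if ref is None:
            continue
        qs = [
            ev.t
            for ev in s.flags
            if ev.source == "moderator"
            and ev.kind in ("protocol_question", "safety_question")
            and ev.t <= ref.t
        ]
        if not qs:
            continue
        delays.append(ref.t - max(qs))
    arr = np.asarray(delays)
    if arr.size == 0:
        return LatencyStats(n=0, mean=None, sd=None)
    mean, sd = _stats(arr)
    return LatencyStats(n=int(arr.size), mean=mean, sd=sd)


@dataclass(frozen=True)
class PrevalenceSummary:
    """SI prevalence with both denominators the literature mixes: rates per
    user visit and per session are reported separately, labeled."""

    n_visits: int
    n_sessions: int
    passive_visits: int
    active_visits: int
    passive_sessions: int
    active_sessions: int
    exposed_visits: int  # visits in SI sessions, disclosers included
    monthly_passive: dict[int, int] = field(default_factory=dict)
    monthly_active: dict[int, int] = field(default_factory=dict)
    monthly_sessions: dict[int, int] = field(default_factory=dict)

    @property
    def passive_rate_visits(self) -> float:
        return self.passive_visits / self.n_visits if self.n_visits else 0.0

    @property
    def active_rate_visits(self) -> float:
        return self.active_visits / self.n_visits if self.n_visits else 0.0

    @property
    def passive_rate_sessions(self) -> float:
        return self.passive_sessions / self.n_sessions if self.n_sessions else 0.0

    @property
    def active_rate_sessions(self) -> float:
        return self.active_sessions / self.n_sessions if self.n_sessions else 0.0

    @property
    def exposure_rate(self) -> float:
        """Fraction of visits that disclosed SI or shared a session with a
        discloser."""
        return self.exposed_visits / self.n_visits if self.n_visits else 0.0

    @property
    def passive_active_ratio(self) -> Optional[float]:
        return self.passive_visits / self.active_visits if self.active_visits else None

    def ratio_label(self, decimals: int = 1) -> Optional[str]:
        r = self.passive_active_ratio
        return None if r is None else f"{round(r, decimals):.{decimals}f}:1"

    @classmethod
    def from_counts(
        cls,
        *,
        passive: int,
        active: int,
        total_visits: int,
        exposed_visits: int = 0,
        total_sessions: int = 0,
        passive_sessions: int = 0,
        active_sessions: int = 0,
    ) -> "PrevalenceSummary":
        """Build directly from published-style counts (e.g. 8,929 passive and
        5,472 active disclosures over 449,946 visits)."""
        return cls(
            n_visits=total_visits,
            n_sessions=total_sessions,
            passive_visits=passive,
            active_visits=active,
            passive_sessions=passive_sessions,
            active_sessions=active_sessions,
            exposed_visits=exposed_visits,
        )


def prevalence_summary(corpus: Corpus) -> PrevalenceSummary:
    sessions = corpus.session_by_id()
    passive_v = sum(1 for v in corpus.visits if v.group == "passive_si")
    active_v = sum(1 for v in corpus.visits if v.group == "active_si")
    exposed_v = sum(
        1 for v in corpus.visits if sessions[v.session_id].si_label != "none"
    )
    monthly_p: dict[int, int] = {}
    monthly_a: dict[int, int] = {}
    monthly_s: dict[int, int] = {}
    passive_s = active_s = 0
    for s in corpus.sessions:
        monthly_s[s.month] = monthly_s.get(s.month, 0) + 1
        if s.si_label == "passive":
            passive_s += 1
            monthly_p[s.month] = monthly_p.get(s.month, 0) + 1
        elif s.si_label == "active":
            active_s += 1
            monthly_a[s.month] = monthly_a.get(s.month, 0) + 1
    return PrevalenceSummary(
        n_visits=len(corpus.visits),
        n_sessions=len(corpus.sessions),
        passive_visits=passive_v,
        active_visits=active_v,
        passive_sessions=passive_s,
        active_sessions=active_s,
        exposed_visits=exposed_v,
        monthly_passive=dict(sorted(monthly_p.items())),
        monthly_active=dict(sorted(monthly_a.items())),
        monthly_sessions=dict(sorted(monthly_s.items())),
    )
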