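"""Domain types, corpus I/O, validation, and demographic summaries.

A *corpus* is a set of moderated group-chat sessions plus the user visits
they received.  Each session carries an ordered message stream with
per-message emotion scores (1-10 integers; absence means "emotion not
detected"), a suicidal-ideation (SI) label, and a stream of timed flag
events (AI crisis flags, moderator protocol/safety questions, crisis
referrals).  Visits carry the four-way analysis group label:

* ``passive_si`` / ``active_si`` -- the visit disclosed SI of that class;
* ``exposed_non_si`` -- a non-disclosing visit in a session where a peer
  disclosed SI;
* ``non_exposed_non_si`` -- a visit in a session with no SI disclosure.

The on-disk format is UTF-8 JSON-lines with typed records (``session``,
``visit``, ``message``) grouped per session and deterministically sorted,
so equal corpora serialize byte-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Union

EMOTIONS = ("despair", "loneliness", "helplessness", "depression", "optimism")
NEGATIVE_EMOTIONS = ("despair", "loneliness", "helplessness", "depression")

SI_LABELS = ("none", "passive", "active")
GROUPS = ("passive_si", "active_si", "exposed_non_si", "non_exposed_non_si")
FLAG_SOURCES = ("ai", "moderator")
FLAG_KINDS = ("crisis_flag", "protocol_question", "safety_question", "referral")

MODERATOR_ID = "moderator"


class CorpusParseError(ValueError):
    """Raised when a corpus file contains a malformed record."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class CorpusValidationError(ValueError):
    """Raised when a parsed corpus violates a structural invariant."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        preview = "; ".join(violations[:5])
        more = "" if len(violations) <= 5 else f" (+{len(violations) - 5} more)"
        super().__init__(f"{len(violations)} violation(s): {preview}{more}")


@dataclass(slots=True)
class Message:
    session_id: str
    user_id: str
    role: str  # "participant" | "moderator"
    t: float  # seconds since session start
    index: int  # 0-based order within session
    text: str
    emotions: dict[str, int] = field(default_factory=dict)


@dataclass(slots=True)
class FlagEvent:
    source: str  # "ai" | "moderator"
    kind: str  # "crisis_flag" | "protocol_question" | "safety_question" | "referral"
    t: float


@dataclass(slots=True)
class ChatSession:
    session_id: str
    month: int  # 1-12
    messages: list[Message] = field(default_factory=list)
    si_label: str = "none"
    si_discloser: Optional[str] = None
    topic: str = "other"
    flags: list[FlagEvent] = field(default_factory=list)

    def participant_messages(self, user_id: str) -> list[Message]:
        return [m for m in self.messages if m.user_id == user_id]

    def first_flag(self, source: str, kind: str) -> Optional[FlagEvent]:
        for ev in self.flags:
            if ev.source == source and ev.kind == kind:
                return ev
        return None

    def last_flag(self, source: str, kind: str) -> Optional[FlagEvent]:
        hit = None
        for ev in self.flags:
            if ev.source == source and ev.kind == kind:
                hit = ev
        return hit


@dataclass(slots=True)
class UserVisit:
    user_id: str
    session_id: str
    group: str
    demographics: Optional[dict] = None  # keys: gender, race, age (all optional)


@dataclass(slots=True)
class Corpus:
    sessions: list[ChatSession] = field(default_factory=list)
    visits: list[UserVisit] = field(default_factory=list)

    def session_by_id(self) -> dict[str, ChatSession]:
        return {s.session_id: s for s in self.sessions}

    def visits_by_session(self) -> dict[str, list[UserVisit]]:
        out: dict[str, list[UserVisit]] = {}
        for v in self.visits:
            out.setdefault(v.session_id, []).append(v)
        return out


# ---------------------------------------------------------------------------
# Validation

def _validate_message(m: Message, prev_t: float, out: list[str]) -> float:
    where = f"session {m.session_id} message {m.index}"
    if m.role not in ("participant", "moderator"):
        out.append(f"{where}: unknown role {m.role!r}")
    if m.t < 0:
        out.append(f"{where}: negative time t={m.t}")
    if m.t < prev_t:
        out.append(f"{where}: time decreases ({m.t} < {prev_t}) in session {m.session_id}")
    for name, score in m.emotions.items():
        if name not in EMOTIONS:
            out.append(f"{where}: field 'emotions': unknown emotion {name!r}")
        if not isinstance(score, int) or isinstance(score, bool) or not (1 <= score <= 10):
            out.append(
                f"{where}: field 'emotions': score {score!r} for {name!r} "
                "outside integer range [1, 10] (0/absent must be omitted)"
            )
    return max(prev_t, m.t)


def validate_corpus(
    corpus: Corpus,
    *,
    min_participant_messages: int = 3,
) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    ``min_participant_messages`` is the analysis-inclusion rule: a session
    must have at least that many messages from at least one participant.
    Reports rather than raises; an empty list means the corpus is valid.
    """
    out: list[str] = []
    seen_sessions: set[str] = set()
    visits_by_session = corpus.visits_by_session()

    for s in corpus.sessions:
        if s.session_id in seen_sessions:
            out.append(f"duplicate session id {s.session_id}")
        seen_sessions.add(s.session_id)
        if not (1 <= s.month <= 12):
            out.append(f"session {s.session_id}: month {s.month} outside 1-12")
        if s.si_label not in SI_LABELS:
            out.append(f"session {s.session_id}: unknown si_label {s.si_label!r}")
        if s.si_label != "none" and s.si_discloser is None:
            out.append(f"session {s.session_id}: si_label={s.si_label} but si_discloser unset")

        session_visits = {v.user_id for v in visits_by_session.get(s.session_id, [])}
        if s.si_discloser is not None and s.si_discloser not in session_visits:
            out.append(f"session {s.session_id}: si_discloser {s.si_discloser!r} has no visit")

        prev_t = 0.0
        per_user: dict[str, int] = {}
        for i, m in enumerate(s.messages):
            if m.index != i:
                out.append(f"session {s.session_id}: message index {m.index} != position {i}")
            if m.session_id != s.session_id:
                out.append(f"session {s.session_id}: message {m.index} carries session_id {m.session_id!r}")
            prev_t = _validate_message(m, prev_t, out)
            if m.role == "participant":
                per_user[m.user_id] = per_user.get(m.user_id, 0) + 1
                if m.user_id not in session_visits:
                    out.append(
                        f"session {s.session_id} message {m.index}: user {m.user_id!r} has no visit"
                    )
            elif m.user_id != MODERATOR_ID:
                out.append(
                    f"session {s.session_id} message {m.index}: moderator message from {m.user_id!r}"
                )

        if not per_user or max(per_user.values()) < min_participant_messages:
            out.append(
                f"session {s.session_id}: inclusion rule violated - no participant "
                f"contributed at least {min_participant_messages} messages"
            )

        n_ai_flags = sum(1 for ev in s.flags if ev.source == "ai" and ev.kind == "crisis_flag")
        if n_ai_flags > 1:
            out.append(f"session {s.session_id}: {n_ai_flags} ai crisis_flag events (max 1)")
        for ev in s.flags:
            if ev.source not in FLAG_SOURCES or ev.kind not in FLAG_KINDS:
                out.append(f"session {s.session_id}: unknown flag event {ev.source}/{ev.kind}")
            if ev.t < 0:
                out.append(f"session {s.session_id}: flag {ev.source}/{ev.kind} at negative time")
            if ev.kind == "referral" and s.si_label != "active":
                out.append(f"session {s.session_id}: referral event in non-active session")

    sessions = {s.session_id: s for s in corpus.sessions}
    seen_visits: set[tuple[str, str]] = set()
    for v in corpus.visits:
        key = (v.session_id, v.user_id)
        if key in seen_visits:
            out.append(f"duplicate visit {v.user_id} in session {v.session_id}")
        seen_visits.add(key)
        s = sessions.get(v.session_id)
        if s is None:
            out.append(f"visit {v.user_id}: unknown session {v.session_id}")
            continue
        if v.group not in GROUPS:
            out.append(f"visit {v.user_id} in {v.session_id}: unknown group {v.group!r}")
            continue
        is_discloser = s.si_discloser == v.user_id and s.si_label != "none"
        expected = (
            f"{s.si_label}_si"
            if is_discloser
            else ("exposed_non_si" if s.si_label != "none" else "non_exposed_non_si")
        )
        if v.group != expected:
            out.append(
                f"visit {v.user_id} in {v.session_id}: group {v.group!r} "
                f"inconsistent with session label (expected {expected!r})"
            )
    return out


# ---------------------------------------------------------------------------
# Serialization

def _message_record(m: Message) -> dict:
    return {
        "kind": "message",
        "session_id": m.session_id,
        "user_id": m.user_id,
        "role": m.role,
        "t": m.t,
        "index": m.index,
        "text": m.text,
        "emotions": m.emotions,
    }


def _session_record(s: ChatSession) -> dict:
    return {
        "kind": "session",
        "session_id": s.session_id,
        "month": s.month,
        "si_label": s.si_label,
        "si_discloser": s.si_discloser,
        "topic": s.topic,
        "flags": [{"source": ev.source, "kind": ev.kind, "t": ev.t} for ev in s.flags],
    }


def _visit_record(v: UserVisit) -> dict:
    return {
        "kind": "visit",
        "session_id": v.session_id,
        "user_id": v.user_id,
        "group": v.group,
        "demographics": v.demographics,
    }


def write_corpus(corpus: Corpus, path: Union[str, Path, IO[str]]) -> None:
    """Serialize deterministically: sessions sorted by id, each followed by
    its visits (sorted by user id) and messages (in order).  Equal corpora
    produce byte-identical files."""
    visits_by_session = corpus.visits_by_session()

    def emit(fh: IO[str]) -> None:
        for s in sorted(corpus.sessions, key=lambda s: s.session_id):
            fh.write(json.dumps(_session_record(s), sort_keys=True, ensure_ascii=False) + "\n")
            for v in sorted(visits_by_session.get(s.session_id, []), key=lambda v: v.user_id):
                fh.write(json.dumps(_visit_record(v), sort_keys=True, ensure_ascii=False) + "\n")
            for m in s.messages:
                fh.write(json.dumps(_message_record(m), sort_keys=True, ensure_ascii=False) + "\n")

    if hasattr(path, "write"):
        emit(path)  # type: ignore[arg-type]
    else:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            emit(fh)


def _require(rec: dict, key: str, lineno: int):
    if key not in rec:
        raise CorpusParseError(lineno, f"record missing field {key!r}")
    return rec[key]


def read_corpus(path: Union[str, Path, IO[str]], *, validate: bool = True) -> Corpus:
    """Parse a JSON-lines corpus file.

    Malformed records raise :class:`CorpusParseError` naming the line;
    invariant violations raise :class:`CorpusValidationError` listing the
    offending fields (pass ``validate=False`` to skip the full check).
    """
    sessions: list[ChatSession] = []
    visits: list[UserVisit] = []
    by_id: dict[str, ChatSession] = {}

    def consume(fh: IO[str]) -> None:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(lineno, f"invalid JSON: {exc.msg}") from exc
            if not isinstance(rec, dict):
                raise CorpusParseError(lineno, "record is not a JSON object")
            kind = _require(rec, "kind", lineno)
            if kind == "session":
                flags = [
                    FlagEvent(source=f["source"], kind=f["kind"], t=float(f["t"]))
                    for f in rec.get("flags", [])
                ]
                s = ChatSession(
                    session_id=_require(rec, "session_id", lineno),
                    month=int(_require(rec, "month", lineno)),
                    si_label=_require(rec, "si_label", lineno),
                    si_discloser=rec.get("si_discloser"),
                    topic=rec.get("topic", "other"),
                    flags=flags,
                )
                sessions.append(s)
                by_id[s.session_id] = s
            elif kind == "visit":
                visits.append(
                    UserVisit(
                        user_id=_require(rec, "user_id", lineno),
                        session_id=_require(rec, "session_id", lineno),
                        group=_require(rec, "group", lineno),
                        demographics=rec.get("demographics"),
                    )
                )
            elif kind == "message":
                emotions_raw = rec.get("emotions", {})
                if not isinstance(emotions_raw, dict):
                    raise CorpusParseError(lineno, "field 'emotions' is not an object")
                emotions: dict[str, int] = {}
                for name, score in emotions_raw.items():
                    if (
                        name not in EMOTIONS
                        or not isinstance(score, int)
                        or isinstance(score, bool)
                        or not (1 <= score <= 10)
                    ):
                        raise CorpusParseError(
                            lineno,
                            f"field 'emotions': invalid entry {name!r}: {score!r} "
                            "(scores are integers in [1, 10]; 0/absent is omitted)",
                        )
                    emotions[name] = score
                sid = _require(rec, "session_id", lineno)
                if sid not in by_id:
                    raise CorpusParseError(lineno, f"message references unknown session {sid!r}")
                m = Message(
                    session_id=sid,
                    user_id=_require(rec, "user_id", lineno),
                    role=_require(rec, "role", lineno),
                    t=float(_require(rec, "t", lineno)),
                    index=int(_require(rec, "index", lineno)),
                    text=rec.get("text", ""),
                    emotions=emotions,
                )
                by_id[sid].messages.append(m)
            else:
                raise CorpusParseError(lineno, f"unknown record kind {kind!r}")

    if hasattr(path, "read"):
        consume(path)  # type: ignore[arg-type]
    else:
        with open(path, "r", encoding="utf-8") as fh:
            consume(fh)

    corpus = Corpus(sessions=sessions, visits=visits)
    if validate:
        violations = validate_corpus(corpus)
        if violations:
            raise CorpusValidationError(violations)
    return corpus


def write_messages_csv(corpus: Corpus, path: Union[str, Path]) -> None:
    """Interoperability export: one CSV row per message, emotion scores as
    columns (empty cell = not detected)."""
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["session_id", "index", "user_id", "role", "t", "text", *EMOTIONS]
        )
        for s in sorted(corpus.sessions, key=lambda s: s.session_id):
            for m in s.messages:
                writer.writerow(
                    [
                        m.session_id,
                        m.index,
                        m.user_id,
                        m.role,
                        m.t,
                        m.text,
                        *[m.emotions.get(e, "") for e in EMOTIONS],
                    ]
                )


# ---------------------------------------------------------------------------
# Demographics

@dataclass
class DemographicSummary:
    n_visits: int
    non_disclosure_rate: float  # fraction of visits with no demographics at all
    categories: dict[str, dict[str, float]]  # attribute -> category -> proportion of disclosers
    category_counts: dict[str, dict[str, int]]
    age: Optional[dict[str, float]]  # median, mean, sd, n


def _summarize(visits: Iterable[UserVisit]) -> DemographicSummary:
    visits = list(visits)
    n = len(visits)
    disclosed = [v for v in visits if v.demographics]
    non_disclosure = 1.0 - (len(disclosed) / n) if n else 1.0

    categories: dict[str, dict[str, float]] = {}
    counts: dict[str, dict[str, int]] = {}
    for attr in ("gender", "race"):
        attr_counts: dict[str, int] = {}
        for v in disclosed:
            val = (v.demographics or {}).get(attr)
            if val is not None:
                attr_counts[val] = attr_counts.get(val, 0) + 1
        total = sum(attr_counts.values())
        counts[attr] = dict(sorted(attr_counts.items()))
        categories[attr] = (
            {k: c / total for k, c in sorted(attr_counts.items())} if total else {}
        )

    ages = [
        float((v.demographics or {}).get("age"))
        for v in disclosed
        if (v.demographics or {}).get("age") is not None
    ]
    age = None
    if ages:
        import numpy as np

        arr = np.asarray(ages)
        age = {
            "median": float(np.median(arr)),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "n": len(arr),
        }
    return DemographicSummary(
        n_visits=n,
        non_disclosure_rate=non_disclosure,
        categories=categories,
        category_counts=counts,
        age=age,
    )


def summarize_demographics(
    visits: Iterable[UserVisit], *, by_group: bool = False
) -> Union[DemographicSummary, dict[str, DemographicSummary]]:
    """Proportions of each category among *disclosing* visits (they sum to 1
    per attribute); the non-disclosure rate is reported separately; age
    summaries use only visits with an age on record."""
    visits = list(visits)
    if not by_group:
        return _summarize(visits)
    out: dict[str, DemographicSummary] = {}
    for g in GROUPS:
        sub = [v for v in visits if v.group == g]
        if sub:
            out[g] = _summarize(sub)
    return out
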