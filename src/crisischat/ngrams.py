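"""N-gram phrase extraction and ranking for active vs passive SI language.

Messages are lowercased, punctuation-stripped (apostrophes kept, so
"don't" stays one token) and windowed into 2-5 token n-grams.  Candidates
are scored against the whole session's term profile by a pluggable ranker;
the shipped default is a deterministic term-frequency cosine ranker, and an
embedding model can be swapped in through the same ``score`` interface.
Ranked phrases are counted across sessions and rows below the minimum
frequency (default 2, i.e. "frequency > 1") are dropped.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

from .transcript import ChatSession

_PUNCT = re.compile(r"[^\w\s']")
_APOSTROPHE_VARIANTS = str.maketrans({"’": "'", "‘": "'"})


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace; contractions
    remain single tokens."""
    cleaned = _PUNCT.sub(" ", text.translate(_APOSTROPHE_VARIANTS).lower())
    return cleaned.split()


def candidate_ngrams(text: str, n_min: int = 2, n_max: int = 5) -> list[str]:
    """All token windows of length n_min..n_max, in order of occurrence
    (shorter windows first at each position)."""
    tokens = tokenize(text)
    out = []
    for i in range(len(tokens)):
        for n in range(n_min, n_max + 1):
            if i + n <= len(tokens):
                out.append(" ".join(tokens[i : i + n]))
    return out


class PhraseRanker(Protocol):
    def score(self, phrase: str, context: Counter) -> float:
        """Relevance of ``phrase`` to a session ``context`` term profile."""


@dataclass
class TermFrequencyCosineRanker:
    """Cosine similarity between the phrase's term-frequency vector and the
    session's term-frequency profile.  Deterministic and dependency-free;
    stands behind the same interface an embedding ranker would."""

    def score(self, phrase: str, context: Counter) -> float:
        terms = Counter(phrase.split())
        norm_c = math.sqrt(sum(c * c for c in context.values()))
        norm_p = math.sqrt(sum(c * c for c in terms.values()))
        if norm_c == 0.0 or norm_p == 0.0:
            return 0.0
        dot = sum(c * context.get(t, 0) for t, c in terms.items())
        return dot / (norm_c * norm_p)


def session_context(session: ChatSession, user_id: str | None = None) -> Counter:
    """Term-frequency profile of the session (or one user's messages)."""
    ctx: Counter = Counter()
    for m in session.messages:
        if m.role != "participant":
            continue
        if user_id is not None and m.user_id != user_id:
            continue
        ctx.update(tokenize(m.text))
    return ctx


def rank_phrases(
    messages: Iterable[str],
    context: Counter,
    ranker: PhraseRanker | None = None,
    *,
    top_k: int = 1,
    n_min: int = 2,
    n_max: int = 5,
) -> list[list[str]]:
    """Per message: candidate n-grams scored by the ranker, case-insensitive
    duplicates removed, top-k kept.  Tied scores break by first occurrence,
    so ranking is deterministic given the ranker."""
    ranker = ranker or TermFrequencyCosineRanker()
    out = []
    for text in messages:
        seen: dict[str, float] = {}
        order: list[str] = []
        for phrase in candidate_ngrams(text, n_min, n_max):
            if phrase not in seen:
                seen[phrase] = ranker.score(phrase, context)
                order.append(phrase)
        ranked = sorted(order, key=lambda ph: (-seen[ph], order.index(ph)))
        out.append(ranked[:top_k])
    return out


@dataclass
class PhraseTable:
    si_class: str  # "active" | "passive"
    rows: list[tuple[str, int]]  # (phrase, frequency), sorted desc, ties alphabetical

    def top(self, k: int = 10) -> list[tuple[str, int]]:
        return self.rows[:k]

    def as_dict(self) -> dict[str, int]:
        return dict(self.rows)


def phrase_frequency_table(
    sessions: Sequence[ChatSession],
    si_class: str,
    *,
    min_freq: int = 2,
    ranker: PhraseRanker | None = None,
    top_k: int = 1,
    discloser_only: bool = True,
) -> PhraseTable:
    """Count ranked phrases across the discloser messages of one SI class.

    Rows with frequency below ``min_freq`` are dropped; remaining rows sort
    by descending frequency, alphabetical on ties.
    """
    if si_class not in ("active", "passive"):
        raise ValueError(f"si_class must be 'active' or 'passive', got {si_class!r}")
    counts: Counter = Counter()
    for s in sessions:
        if s.si_label != si_class:
            continue
        if discloser_only:
            if s.si_discloser is None:
                continue
            texts = [m.text for m in s.participant_messages(s.si_discloser)]
            ctx = session_context(s, s.si_discloser)
        else:
            texts = [m.text for m in s.messages if m.role == "participant"]
            ctx = session_context(s)
        for ranked in rank_phrases(texts, ctx, ranker, top_k=top_k):
            counts.update(ranked)
    rows = [(ph, c) for ph, c in counts.items() if c >= min_freq]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return PhraseTable(si_class=si_class, rows=rows)
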