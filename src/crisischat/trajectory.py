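"""Emotion-trajectory normalization onto a common 0-100% progression scale.

Chats vary in length, so each user-visit's scored messages for one emotion
are placed at progression knots i/(m-1) and linearly interpolated onto a
shared grid (101 points by default: 0%, 1%, ..., 100%).  Aggregating the
per-visit curves pointwise gives the population trajectory; the begin/end
percent change summarizes it (reduction for the negative emotions,
increase for optimism).

Eligibility mirrors the analysis inclusion rule: a visit qualifies for an
emotion only if the focal user's first three messages contain a score >= 5
for it (conversations must begin with measurable distress), and active-SI
disclosers are always excluded because the crisis referral changes the
conversation's structure and goals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .transcript import EMOTIONS, ChatSession, Corpus, GROUPS

logger = logging.getLogger(__name__)

DEFAULT_GRID_POINTS = 101


@dataclass
class TrajectoryCurve:
    emotion: str
    grid: np.ndarray  # progression fractions in [0, 1], endpoints included
    values: np.ndarray  # pointwise mean score
    sd: np.ndarray  # pointwise dispersion
    n: int  # curves aggregated

    @property
    def begin(self) -> float:
        return float(self.values[0])

    @property
    def end(self) -> float:
        return float(self.values[-1])


def focal_visits(corpus: Corpus, group: str) -> list[tuple[ChatSession, str]]:
    """The (session, user) pairs whose messages define the group's
    trajectories: the discloser for the SI groups, each non-disclosing
    visit itself for the exposure groups."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    sessions = corpus.session_by_id()
    out = []
    for v in corpus.visits:
        if v.group == group:
            out.append((sessions[v.session_id], v.user_id))
    return out


def eligible_visits(
    corpus: Corpus,
    emotion: str,
    *,
    group: str,
    threshold: int = 5,
    window: int = 3,
    threshold_emotions: Optional[Sequence[str]] = None,
) -> list[tuple[str, str]]:
    """(session_id, user_id) pairs of ``group`` eligible for ``emotion``.

    A pair qualifies iff the maximum score over the focal user's first
    ``window`` messages reaches ``threshold`` for at least one emotion in
    ``threshold_emotions`` (default: the analyzed emotion itself).
    Active-SI visits never qualify.
    """
    if emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion {emotion!r}")
    gate = tuple(threshold_emotions) if threshold_emotions is not None else (emotion,)
    for e in gate:
        if e not in EMOTIONS:
            raise ValueError(f"unknown emotion {e!r} in threshold_emotions")
    if group == "active_si":
        return []
    out = []
    for session, user_id in focal_visits(corpus, group):
        first = session.participant_messages(user_id)[:window]
        best = max(
            (m.emotions[e] for m in first for e in gate if e in m.emotions),
            default=0,
        )
        if best >= threshold:
            out.append((session.session_id, user_id))
    return out


def eligible_sessions(
    corpus: Corpus,
    emotion: str,
    *,
    group: str,
    threshold: int = 5,
    window: int = 3,
    threshold_emotions: Optional[Sequence[str]] = None,
) -> list[str]:
    """Session ids of the eligible user-visits (see :func:`eligible_visits`)."""
    return [
        sid
        for sid, _ in eligible_visits(
            corpus,
            emotion,
            group=group,
            threshold=threshold,
            window=window,
            threshold_emotions=threshold_emotions,
        )
    ]


def interpolate_trajectory(
    session: ChatSession,
    user_id: str,
    emotion: str,
    grid_points: int = DEFAULT_GRID_POINTS,
) -> np.ndarray:
    """Piecewise-linear curve of one user's scores on the progression grid.

    The user's m scored messages sit at knots i/(m-1); the curve is exact on
    its knots and its endpoints equal the first and last scores.  Raises
    ``ValueError`` if fewer than 2 scored messages exist.
    """
    if emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion {emotion!r}")
    scores = [
        m.emotions[emotion]
        for m in session.participant_messages(user_id)
        if emotion in m.emotions
    ]
    if len(scores) < 2:
        raise ValueError(
            f"user {user_id} in session {session.session_id} has "
            f"{len(scores)} scored message(s) for {emotion!r}; need >= 2"
        )
    knots = np.linspace(0.0, 1.0, len(scores))
    grid = np.linspace(0.0, 1.0, grid_points)
    return np.interp(grid, knots, np.asarray(scores, dtype=float))


def trajectory_curves(
    corpus: Corpus,
    pairs: Iterable[tuple[str, str]],
    emotion: str,
    grid_points: int = DEFAULT_GRID_POINTS,
) -> tuple[list[np.ndarray], list[tuple[str, str]]]:
    """Interpolate every (session_id, user_id) pair that has enough scored
    messages; pairs skipped (with a logged reason) are dropped from the
    returned pair list so curves and pairs stay aligned."""
    sessions = corpus.session_by_id()
    curves, kept = [], []
    for sid, uid in pairs:
        try:
            curves.append(interpolate_trajectory(sessions[sid], uid, emotion, grid_points))
            kept.append((sid, uid))
        except ValueError as exc:
            logger.info("skipping trajectory: %s", exc)
    return curves, kept


def aggregate_trajectories(curves: Sequence[np.ndarray], emotion: str = "") -> TrajectoryCurve:
    """Pointwise mean and SD over per-visit curves sharing a grid."""
    if not curves:
        raise ValueError("no curves to aggregate")
    lengths = {len(c) for c in curves}
    if len(lengths) != 1:
        raise ValueError(f"grid mismatch: curve lengths {sorted(lengths)}")
    arr = np.vstack(curves)
    grid = np.linspace(0.0, 1.0, arr.shape[1])
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
    return TrajectoryCurve(
        emotion=emotion, grid=grid, values=arr.mean(axis=0), sd=sd, n=arr.shape[0]
    )


def percent_change(curve: TrajectoryCurve, emotion: Optional[str] = None) -> float:
    """Signed percent change between the curve's endpoints.

    Negative emotions report a *reduction*, (begin - end)/begin * 100;
    optimism reports an *increase*, (end - begin)/begin * 100.  Positive
    values therefore mean improvement in both conventions.
    """
    emotion = emotion or curve.emotion
    if emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion {emotion!r}")
    begin, end = curve.begin, curve.end
    if begin <= 0:
        raise ValueError("begin value must be positive for a percent change")
    if emotion == "optimism":
        return (end - begin) / begin * 100.0
    return (begin - end) / begin * 100.0
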