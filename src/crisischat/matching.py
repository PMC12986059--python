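"""Propensity-score estimation and 1:1 greedy caliper matching.

Treatment membership (e.g. passive-SI vs non-SI conversation) is modeled by
logistic regression on two covariates — initial emotional intensity (max
score over the focal user's first three messages) and conversation topic
(one-hot, most frequent level dropped).  Scores are taken to the logit
scale and each treated unit greedily takes its nearest unused control;
pairs farther apart than the caliper (0.01 logit units by default) are
excluded.  Treated units are processed in a seeded random order since the
processing order is otherwise an arbitrary systematic choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np


class PerfectSeparationError(RuntimeError):
    """The likelihood is unbounded (a covariate separates the groups);
    refit with ``ridge=1e-6`` (or larger) to penalize the fit."""


@dataclass(frozen=True)
class MatchRecord:
    id: str
    treated: bool
    initial_intensity: float  # max emotion score over first 3 messages, in [1, 10]
    topic: str


@dataclass
class MatchResult:
    pairs: list[tuple[str, str, float]]  # (treated id, control id, logit distance)
    excluded: list[str]  # treated ids with no within-caliper control
    caliper: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> set[str]:
        out = set()
        for t, c, _ in self.pairs:
            out.add(t)
            out.add(c)
        return out


def _design_matrix(records: Sequence[MatchRecord]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Intercept + intensity + topic dummies with the most frequent topic as
    the dropped reference level (ties on frequency broken alphabetically)."""
    topics: dict[str, int] = {}
    for r in records:
        topics[r.topic] = topics.get(r.topic, 0) + 1
    reference = max(sorted(topics), key=lambda t: topics[t])
    dummy_levels = [t for t in sorted(topics) if t != reference]
    n, k = len(records), 2 + len(dummy_levels)
    X = np.zeros((n, k))
    X[:, 0] = 1.0
    X[:, 1] = [r.initial_intensity for r in records]
    col = {t: 2 + j for j, t in enumerate(dummy_levels)}
    for i, r in enumerate(records):
        if r.topic != reference:
            X[i, col[r.topic]] = 1.0
    y = np.array([1.0 if r.treated else 0.0 for r in records])
    names = ["intercept", "intensity"] + [f"topic[{t}]" for t in dummy_levels]
    return X, y, names


def fit_propensity_coefficients(
    records: Sequence[MatchRecord],
    *,
    ridge: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, list[str]]:
    """Maximum-likelihood logistic fit by iteratively reweighted least
    squares; converged when the gradient's max-norm drops below ``tol``.
    ``ridge`` adds an L2 penalty on the non-intercept coefficients."""
    if not any(r.treated for r in records) or not any(not r.treated for r in records):
        raise ValueError("need at least one treated and one control record")
    X, y, names = _design_matrix(records)
    k = X.shape[1]
    beta = np.zeros(k)
    penalty = np.full(k, ridge)
    penalty[0] = 0.0  # intercept unpenalized
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p) - penalty * beta
        if np.max(np.abs(grad)) < tol:
            break
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X + np.diag(penalty)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise PerfectSeparationError(
                "singular IRLS system; the groups are separable on the "
                "covariates - refit with ridge=1e-6"
            ) from exc
        beta = beta + step
    else:
        if ridge == 0.0:
            eta = np.clip(X @ beta, -35, 35)
            p = 1.0 / (1.0 + np.exp(-eta))
            if np.max(np.abs(X.T @ (y - p))) >= tol:
                raise PerfectSeparationError(
                    "IRLS did not converge in "
                    f"{max_iter} iterations; likely perfect separation - "
                    "refit with ridge=1e-6"
                )
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e6:
        raise PerfectSeparationError(
            "divergent coefficients indicate perfect separation - refit with ridge=1e-6"
        )
    if ridge == 0.0:
        eta = np.clip(X @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        # fitted probabilities equal to the labels => the MLE does not exist
        if np.all(np.abs(y - p) < 1e-6):
            raise PerfectSeparationError(
                "fitted probabilities saturate at the labels (perfect "
                "separation); refit with ridge=1e-6"
            )
    return beta, names


def fit_propensity(
    records: Sequence[MatchRecord], *, ridge: float = 0.0
) -> dict[str, float]:
    """Propensity P(treated | intensity, topic) per record id, in (0, 1)."""
    beta, _ = fit_propensity_coefficients(records, ridge=ridge)
    X, _, _ = _design_matrix(records)
    eta = np.clip(X @ beta, -35, 35)
    p = 1.0 / (1.0 + np.exp(-eta))
    return {r.id: float(pi) for r, pi in zip(records, p)}


_CLIP = 1e-12


def logit(p: float) -> float:
    """log(p / (1 - p)); raises on p outside the open interval (0, 1)."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"logit requires 0 < p < 1, got {p}")
    return math.log(p / (1.0 - p))


def match_pairs(
    records: Sequence[MatchRecord],
    propensities: Mapping[str, float],
    caliper: float = 0.01,
    *,
    rng: Optional[Union[int, np.random.Generator]] = None,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching on |logit difference|, without
    replacement.  Propensities are clipped away from {0, 1} before the logit
    so saturated fits cannot produce infinities; equally distant controls
    tie-break to the lowest unit id.  ``rng`` seeds the random order in
    which treated units choose."""
    missing = [r.id for r in records if r.id not in propensities]
    if missing:
        raise KeyError(f"missing propensities for {len(missing)} record(s), e.g. {missing[0]!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def lg(rid: str) -> float:
        return logit(float(np.clip(propensities[rid], _CLIP, 1.0 - _CLIP)))

    treated = sorted((r.id for r in records if r.treated))
    controls = sorted((r.id for r in records if not r.treated))
    c_logit = np.array([lg(c) for c in controls])
    c_ids = np.array(controls)
    alive = np.ones(len(controls), dtype=bool)

    order = rng.permutation(len(treated))
    pairs: list[tuple[str, str, float]] = []
    excluded: list[str] = []
    for idx in order:
        t = treated[idx]
        if not alive.any():
            excluded.append(t)
            continue
        d = np.abs(c_logit - lg(t))
        d[~alive] = np.inf
        dmin = d.min()
        if dmin > caliper:
            excluded.append(t)
            continue
        cand = np.flatnonzero(d == dmin)
        j = cand[np.argmin(c_ids[cand])]  # deterministic tie-break: lowest id
        alive[j] = False
        pairs.append((t, str(c_ids[j]), float(dmin)))

    pairs.sort(key=lambda p: p[0])
    excluded.sort()
    assert all(d <= caliper for _, _, d in pairs)
    return MatchResult(pairs=pairs, excluded=excluded, caliper=caliper)


@dataclass
class BalanceRow:
    covariate: str
    smd_before: Optional[float]
    smd_after: Optional[float]


def standardized_mean_diff(
    records: Sequence[MatchRecord], result: MatchResult
) -> list[BalanceRow]:
    """SMD = (mean_T - mean_C) / pooled SD per covariate (intensity plus a
    one-hot column per topic), before matching (all units) and after
    (matched units only).  Pooled SD is computed on the *unmatched* groups
    in both columns, the conventional balance diagnostic."""
    topics = sorted({r.topic for r in records})

    def columns(rs: Sequence[MatchRecord]) -> dict[str, np.ndarray]:
        cols = {"intensity": np.array([r.initial_intensity for r in rs])}
        for t in topics:
            cols[f"topic[{t}]"] = np.array([1.0 if r.topic == t else 0.0 for r in rs])
        return cols

    def smd(x_t: np.ndarray, x_c: np.ndarray, pool_t: np.ndarray, pool_c: np.ndarray):
        sd = math.sqrt(
            (pool_t.var(ddof=1) if len(pool_t) > 1 else 0.0) / 2
            + (pool_c.var(ddof=1) if len(pool_c) > 1 else 0.0) / 2
        )
        if sd == 0.0:
            return 0.0 if x_t.mean() == x_c.mean() else None
        return float((x_t.mean() - x_c.mean()) / sd)

    by_id = {r.id: r for r in records}
    all_t = [r for r in records if r.treated]
    all_c = [r for r in records if not r.treated]
    m_t = [by_id[t] for t, _, _ in result.pairs]
    m_c = [by_id[c] for _, c, _ in result.pairs]
    if not result.pairs:
        raise ValueError("no matched pairs to assess balance on")

    before_t, before_c = columns(all_t), columns(all_c)
    after_t, after_c = columns(m_t), columns(m_c)
    rows = []
    for name in before_t:
        rows.append(
            BalanceRow(
                covariate=name,
                smd_before=smd(before_t[name], before_c[name], before_t[name], before_c[name]),
                smd_after=smd(after_t[name], after_c[name], before_t[name], before_c[name]),
            )
        )
    return rows
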