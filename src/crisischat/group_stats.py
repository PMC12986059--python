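"""Group comparisons: Mann-Whitney U baselines and the ANCOVA
group-by-time interaction on normalized conversation progression.

The Mann-Whitney U is computed from rank sums with midranks for ties.  For
small problems without ties (n_a * n_b <= 200) the p-value comes from the
exact null distribution of the rank sum (counting recurrence); otherwise
the normal approximation with tie-corrected variance and a continuity
correction is used.  The ANCOVA is an ordinary least-squares fit of

    score ~ 1 + time + group + group:time

where time is the 0-1 conversation progression; the group-by-time
interaction coefficient tests whether the two groups' emotional
trajectories have different slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata

from .transcript import Corpus
from .trajectory import focal_visits

EXACT_PAIR_LIMIT = 200


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of sample a
    z: float  # tie-corrected, continuity-corrected normal deviate
    p: float  # two-sided
    method: str  # "exact" | "normal"


def _exact_rank_sum_counts(n1: int, n: int) -> np.ndarray:
    """counts[w] = number of n1-subsets of ranks 1..n with rank sum w."""
    w_max = n1 * n
    # dp[k][w]: subsets of size k from ranks seen so far with sum w
    dp = np.zeros((n1 + 1, w_max + 1))
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, : w_max + 1 - r]
    return dp[n1]


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test; U is reported for ``sample_a``.

    U_a + U_b = n_a * n_b always; U_a equals the pair count
    #{(i,j): a_i > b_j} + half the number of ties across samples.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)  # midranks for ties
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    mu = n_a * n_b / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var > 0:
        cc = 0.5 if u_a != mu else 0.0
        z = (u_a - mu - math.copysign(cc, u_a - mu)) / math.sqrt(var)
    else:
        z = 0.0

    if not has_ties and n_a * n_b <= EXACT_PAIR_LIMIT:
        counts = _exact_rank_sum_counts(n_a, n)
        total = counts.sum()
        offset = n_a * (n_a + 1) // 2
        u_vals = np.arange(counts.size) - offset  # U for each rank sum
        u_int = int(round(u_a))
        p_le = counts[u_vals <= u_int].sum() / total
        p_ge = counts[u_vals >= u_int].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return MannWhitneyResult(u=u_a, z=z, p=p, method="exact")

    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return MannWhitneyResult(u=u_a, z=z, p=p, method="normal")


@dataclass
class AncovaResult:
    coefficients: dict[str, float]  # intercept, time, group, group_time
    std_errors: dict[str, float]
    t_interaction: float
    p_interaction: float  # two-sided, t distribution with n - 4 df
    slopes: dict[int, float]  # fitted slope per group (0 and 1)
    n_points: int
    n_sessions: int
    df_resid: float


def ancova_interaction(
    points: pd.DataFrame, *, cluster_by_session: bool = False
) -> AncovaResult:
    """OLS of score on time, group and their interaction.

    ``points`` needs columns ``session_id``, ``group`` (0/1), ``time``
    (in [0, 1]) and ``score`` — typically each session's interpolated grid
    values so all sessions contribute equally many points.  Residuals are
    treated as independent by default; ``cluster_by_session=True`` switches
    to a cluster-robust covariance.
    """
    req = {"session_id", "group", "time", "score"}
    missing = req - set(points.columns)
    if missing:
        raise ValueError(f"points missing columns {sorted(missing)}")
    g = points["group"].to_numpy(dtype=float)
    t = points["time"].to_numpy(dtype=float)
    y = points["score"].to_numpy(dtype=float)
    if set(np.unique(g)) != {0.0, 1.0}:
        raise ValueError("both groups (0 and 1) must be present")
    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct time values")

    X = np.column_stack([np.ones_like(t), t, g, g * t])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("rank-deficient design (collinear time/group columns)")
    if cluster_by_session:
        model = sm.OLS(y, X).fit(
            cov_type="cluster", cov_kwds={"groups": points["session_id"]}, use_t=True
        )
    else:
        model = sm.OLS(y, X).fit()
    names = ["intercept", "time", "group", "group_time"]
    coef = dict(zip(names, model.params))
    return AncovaResult(
        coefficients=coef,
        std_errors=dict(zip(names, model.bse)),
        t_interaction=float(model.tvalues[3]),
        p_interaction=float(model.pvalues[3]),
        slopes={0: coef["time"], 1: coef["time"] + coef["group_time"]},
        n_points=int(len(y)),
        n_sessions=int(points["session_id"].nunique()),
        df_resid=float(model.df_resid),
    )


@dataclass
class GroupBaseline:
    group: str
    n_begin: int
    n_end: int
    begin_mean: float
    begin_sd: float
    end_mean: float
    end_sd: float


@dataclass
class BaselineComparison:
    emotion: str
    a: GroupBaseline
    b: GroupBaseline
    mann_whitney: MannWhitneyResult


def _group_begin_end(
    corpus: Corpus, group: str, emotion: str, min_messages: int
) -> tuple[list[int], list[int]]:
    begins, ends = [], []
    for session, user_id in focal_visits(corpus, group):
        msgs = session.participant_messages(user_id)
        if len(msgs) < min_messages:
            continue
        first = msgs[0].emotions.get(emotion)
        last = msgs[-1].emotions.get(emotion)
        if first is not None:
            begins.append(first)
        if last is not None:
            ends.append(last)
    return begins, ends


def baseline_comparison(
    corpus: Corpus,
    emotion: str,
    groups: tuple[str, str],
    *,
    min_messages: int = 5,
) -> BaselineComparison:
    """Begin/end score summaries per group plus a Mann-Whitney test on the
    baselines.  Baseline = the focal user's *first* message score, after
    restricting to users who contributed at least ``min_messages`` messages;
    absent scores (emotion not detected) are excluded, never imputed as 0.
    """
    summaries = []
    samples = []
    for g in groups:
        begins, ends = _group_begin_end(corpus, g, emotion, min_messages)
        if not begins:
            raise ValueError(
                f"group {g!r} has no usable baseline scores for {emotion!r} "
                f"(after the >= {min_messages}-message filter)"
            )
        b = np.asarray(begins, dtype=float)
        e = np.asarray(ends, dtype=float)
        summaries.append(
            GroupBaseline(
                group=g,
                n_begin=b.size,
                n_end=e.size,
                begin_mean=float(b.mean()),
                begin_sd=float(b.std(ddof=1)) if b.size > 1 else 0.0,
                end_mean=float(e.mean()) if e.size else float("nan"),
                end_sd=float(e.std(ddof=1)) if e.size > 1 else 0.0,
            )
        )
        samples.append(begins)
    mw = mann_whitney(samples[0], samples[1])
    return BaselineComparison(emotion=emotion, a=summaries[0], b=summaries[1], mann_whitney=mw)
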