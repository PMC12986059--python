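"""Synthetic corpus generator calibrated to the study's statistical structure.

The generator emulates a year of moderated small-group chat sessions:

* SI prevalence per user visit (defaults: 1.98% passive, 1.21% active);
* the AI-flag model (sensitivity of the AI flag given a moderator flag,
  false-positive rate among unflagged sessions);
* AI-first flag ordering and moderator follow-up latencies (lognormal,
  moment-matched to the reported mean/SD);
* crisis-referral delay after the moderator's final determination question;
* per-group begin/end emotion levels with a linear latent trajectory,
  additive noise, integer 1-10 scores and a per-score absence probability;
* SI phrase lexicons injected into discloser messages with frequencies
  proportional to the reported phrase tables;
* voluntary demographic disclosure (~30%) with per-group category mixes.

Calibration note: emotion scores are ``round(clip(latent + noise, 1, 10))``.
Clipping and rounding would bias the realized mean/SD away from the
configured begin/end levels (the end levels sit ~1.3 SD above the floor),
so the latent Normal parameters are solved numerically such that the
*integer score distribution* has exactly the configured mean and SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.optimize import root
from scipy.stats import norm, truncnorm

from .transcript import (
    EMOTIONS,
    MODERATOR_ID,
    ChatSession,
    Corpus,
    FlagEvent,
    Message,
    UserVisit,
)


class GeneratorConfigError(ValueError):
    """Invalid generator configuration (raised before any sampling)."""


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class LatencySpec:
    mean: float
    sd: float


@dataclass
class FlagModel:
    # P(AI crisis flag | moderator flagged the session) -- the AI flag's
    # sensitivity against the moderator benchmark.
    p_ai_flag_given_si: float = 0.8751
    # P(AI crisis flag | moderator did not flag) = FP count / non-SI sessions.
    p_ai_flag_given_no_si: float = 14735 / 155401
    p_moderator_flag_given_si: float = 1.0


@dataclass
class OrderingModel:
    p_ai_first_active: float = 0.8126
    p_ai_first_passive: float = 0.7752


@dataclass
class EmotionLevels:
    begin_mean: float
    begin_sd: float
    end_mean: float
    end_sd: float


def _passive_levels() -> dict[str, EmotionLevels]:
    return {
        "despair": EmotionLevels(6.82, 1.39, 3.45, 2.26),
        "loneliness": EmotionLevels(7.14, 1.40, 4.34, 2.32),
        "helplessness": EmotionLevels(7.02, 1.40, 4.20, 2.28),
        "depression": EmotionLevels(6.74, 1.33, 3.74, 2.19),
        "optimism": EmotionLevels(2.12, 0.57, 4.09, 2.28),
    }


def _non_si_levels() -> dict[str, EmotionLevels]:
    return {
        "despair": EmotionLevels(6.34, 1.23, 3.17, 1.99),
        "loneliness": EmotionLevels(6.60, 1.26, 4.00, 2.11),
        "helplessness": EmotionLevels(6.48, 1.22, 3.87, 2.06),
        "depression": EmotionLevels(6.23, 1.17, 3.29, 1.92),
        "optimism": EmotionLevels(2.17, 0.59, 4.02, 2.23),
    }


def _exposed_levels() -> dict[str, EmotionLevels]:
    return {
        "despair": EmotionLevels(6.63, 1.38, 3.15, 2.05),
        "loneliness": EmotionLevels(7.02, 1.40, 4.02, 2.15),
        "helplessness": EmotionLevels(6.89, 1.38, 3.91, 2.15),
        "depression": EmotionLevels(6.57, 1.29, 3.27, 1.93),
        "optimism": EmotionLevels(2.17, 0.55, 4.25, 2.32),
    }


def _default_levels() -> dict[str, dict[str, EmotionLevels]]:
    # Active-SI users are excluded from trajectory analyses, so no begin/end
    # levels are reported for them; they reuse the passive-SI profile.
    return {
        "passive_si": _passive_levels(),
        "active_si": _passive_levels(),
        "exposed_non_si": _exposed_levels(),
        "non_exposed_non_si": _non_si_levels(),
    }


@dataclass
class EmotionModel:
    levels: dict[str, dict[str, EmotionLevels]] = field(default_factory=_default_levels)
    noise_sd: float = 0.4  # per-message noise around the latent line
    p_absent: float = 0.2  # per-message, per-emotion "not detected" probability


ACTIVE_LEXICON: list[tuple[str, int]] = [
    ("just wanna die", 261),
    ("feel like dying", 135),
    ("don't want life", 91),
    ("want kill self", 70),
    ("feel like failure", 64),
    ("want end life", 48),
    ("i'm better dead", 29),
]

PASSIVE_LEXICON: list[tuple[str, int]] = [
    ("just feel lonely", 428),
    ("just wanna disappear", 193),
    ("feel like running away", 186),
    ("just feel worthless", 151),
    ("i'm really scared", 137),
    ("just hate life", 122),
    ("think autism social anxiety", 83),
    ("i'm said i'm ugly", 69),
]

FILLER_VOCAB: list[str] = sorted(
    set(
        (
            "today was long and i kept thinking about everything again honestly "
            "not sure how to say this but talking here helps a bit thanks for "
            "listening it has been a rough week at school and home lately trying "
            "to keep going one day at a time you know my sister called me after "
            "class we argued over nothing then felt bad about it later that night "
            "slept badly woke up tired before work still managed some breakfast "
            "coffee with an old friend from town who moved away last spring they "
            "asked what changed since summer told them things got busy new job "
            "different hours less energy most evenings just watch shows or scroll "
            "until late sometimes walk around the park when weather allows music "
            "usually helps too especially older songs remind me of better times "
            "maybe next month will try joining that group everyone keeps "
            "mentioning appreciate people here being patient while figure stuff "
            "out anyway enough rambling wanted share where head is right now"
        ).split()
    )
)


def _default_gender() -> dict[str, dict[str, float]]:
    return {
        "active": {"female": 0.6310, "male": 0.2758, "non_binary": 0.0931},
        "passive": {"female": 0.6467, "male": 0.2755, "non_binary": 0.0778},
        "none": {"female": 0.6360, "male": 0.2929, "non_binary": 0.0711},
    }


def _default_race() -> dict[str, dict[str, float]]:
    return {
        "active": {
            "white": 0.4793, "asian": 0.1515, "hispanic_latino": 0.1209,
            "black": 0.1178, "aian": 0.0598, "mena": 0.0477, "nhpi": 0.0229,
        },
        "passive": {
            "white": 0.4856, "asian": 0.1409, "hispanic_latino": 0.1340,
            "black": 0.1026, "aian": 0.0646, "mena": 0.0499, "nhpi": 0.0225,
        },
        "none": {
            "white": 0.4762, "asian": 0.1453, "hispanic_latino": 0.1348,
            "black": 0.0995, "aian": 0.0713, "mena": 0.0492, "nhpi": 0.0237,
        },
    }


@dataclass
class DemographicsModel:
    p_disclose: float = 0.30
    gender: dict[str, dict[str, float]] = field(default_factory=_default_gender)
    race: dict[str, dict[str, float]] = field(default_factory=_default_race)
    # Age = offset + Gamma(moment-matched); only the reported median/mean/SD
    # shape is emulated, approximately.
    age_offset: float = 13.0
    age_mean: float = 24.0
    age_sd: float = 12.0


def _default_topics() -> dict[str, float]:
    return {
        "relationships": 0.22,
        "anxiety": 0.20,
        "family": 0.15,
        "work_stress": 0.14,
        "loneliness": 0.12,
        "health": 0.09,
        "school": 0.08,
    }


def _default_users_per_session() -> dict[int, float]:
    # up to 5 peers per room; mean 2.7 visits/session
    return {1: 0.25, 2: 0.25, 3: 0.20, 4: 0.15, 5: 0.15}


def _default_latency() -> dict[str, LatencySpec]:
    return {
        "active": LatencySpec(71.32, 89.00),
        "passive": LatencySpec(79.87, 95.71),
        "referral": LatencySpec(245.0, 557.0),
    }


@dataclass
class GeneratorConfig:
    n_sessions: int = 1000
    seed: int = 0
    users_per_session: dict[int, float] = field(default_factory=_default_users_per_session)
    messages_per_user_min: int = 3
    messages_per_user_extra_mean: float = 5.0  # Poisson mean on top of the minimum
    inter_message_mean_s: float = 30.0  # exponential gaps between messages
    prevalence_passive: float = 0.0198  # per user visit
    prevalence_active: float = 0.0121
    flag_model: FlagModel = field(default_factory=FlagModel)
    ordering: OrderingModel = field(default_factory=OrderingModel)
    latency: dict[str, LatencySpec] = field(default_factory=_default_latency)
    latency_distribution: str = "lognormal"  # or "truncnorm"
    emotion_model: EmotionModel = field(default_factory=EmotionModel)
    topics: dict[str, float] = field(default_factory=_default_topics)
    lexicons: dict[str, list[tuple[str, int]]] = field(
        default_factory=lambda: {"active": list(ACTIVE_LEXICON), "passive": list(PASSIVE_LEXICON)}
    )
    filler_vocab: list[str] = field(default_factory=lambda: list(FILLER_VOCAB))
    p_safety_question: float = 0.5  # chance the moderator adds the 24 h safety question
    monthly_weights: Optional[list[float]] = None  # 12 weights; None = uniform

    def validate(self) -> None:
        errs = []
        if self.n_sessions < 0:
            errs.append("n_sessions must be non-negative")
        if abs(sum(self.users_per_session.values()) - 1.0) > 1e-9:
            errs.append("users_per_session probabilities must sum to 1")
        if any(u < 1 or u > 5 for u in self.users_per_session):
            errs.append("users_per_session supports 1..5 users")
        for name in ("prevalence_passive", "prevalence_active", "p_safety_question"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errs.append(f"{name} must lie in [0, 1]")
        u_max = max(self.users_per_session)
        if u_max * (self.prevalence_passive + self.prevalence_active) > 1.0:
            errs.append(
                "prevalence too high: u_max * (passive + active) exceeds 1, so a "
                "session's SI probability would exceed 1"
            )
        fm = self.flag_model
        for name in ("p_ai_flag_given_si", "p_ai_flag_given_no_si", "p_moderator_flag_given_si"):
            if not (0.0 <= getattr(fm, name) <= 1.0):
                errs.append(f"flag_model.{name} must lie in [0, 1]")
        for name in ("p_ai_first_active", "p_ai_first_passive"):
            if not (0.0 <= getattr(self.ordering, name) <= 1.0):
                errs.append(f"ordering.{name} must lie in [0, 1]")
        for kind, spec in self.latency.items():
            if spec.mean <= 0 or spec.sd < 0:
                errs.append(f"latency[{kind!r}]: mean must be > 0 and sd >= 0")
        if self.latency_distribution not in ("lognormal", "truncnorm"):
            errs.append("latency_distribution must be 'lognormal' or 'truncnorm'")
        em = self.emotion_model
        if not (0.0 <= em.p_absent <= 1.0):
            errs.append("emotion_model.p_absent must lie in [0, 1]")
        if em.noise_sd < 0:
            errs.append("emotion_model.noise_sd must be >= 0")
        for group, levels in em.levels.items():
            for emo, lv in levels.items():
                if emo not in EMOTIONS:
                    errs.append(f"emotion_model.levels[{group!r}]: unknown emotion {emo!r}")
                for fname in ("begin_mean", "end_mean"):
                    v = getattr(lv, fname)
                    if not (1.0 <= v <= 10.0):
                        errs.append(
                            f"emotion_model.levels[{group!r}][{emo!r}].{fname} outside [1, 10]"
                        )
                if lv.begin_sd < 0 or lv.end_sd < 0:
                    errs.append(f"emotion_model.levels[{group!r}][{emo!r}]: negative SD")
        if abs(sum(self.topics.values()) - 1.0) > 1e-9:
            errs.append("topic probabilities must sum to 1")
        for cls, lex in self.lexicons.items():
            if cls not in ("active", "passive"):
                errs.append(f"lexicons: unknown SI class {cls!r}")
            if any(w <= 0 for _, w in lex):
                errs.append(f"lexicons[{cls!r}]: weights must be positive")
        if not (0.0 <= self.demographics.p_disclose <= 1.0):
            errs.append("demographics.p_disclose must lie in [0, 1]")
        if self.monthly_weights is not None and (
            len(self.monthly_weights) != 12 or any(w < 0 for w in self.monthly_weights)
        ):
            errs.append("monthly_weights must be 12 non-negative numbers")
        if errs:
            raise GeneratorConfigError("; ".join(errs))

    demographics: DemographicsModel = field(default_factory=DemographicsModel)


# ---------------------------------------------------------------------------
# Integer-score calibration

_SCORES = np.arange(1, 11, dtype=float)


def integer_score_distribution(mu: float, sigma: float) -> np.ndarray:
    """P(score = k), k = 1..10, for score = round(clip(N(mu, sigma), 1, 10))."""
    if sigma < 1e-12:
        p = np.zeros(10)
        p[int(np.clip(np.rint(np.clip(mu, 1, 10)), 1, 10)) - 1] = 1.0
        return p
    upper = np.concatenate([_SCORES[:-1] + 0.5, [np.inf]])
    lower = np.concatenate([[-np.inf], _SCORES[1:] - 0.5])
    return norm.cdf((upper - mu) / sigma) - norm.cdf((lower - mu) / sigma)


def _integer_score_moments(mu: float, sigma: float) -> tuple[float, float]:
    p = integer_score_distribution(mu, sigma)
    m = float(p @ _SCORES)
    v = float(p @ _SCORES**2) - m * m
    return m, math.sqrt(max(v, 0.0))


@lru_cache(maxsize=512)
def latent_score_params(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Latent (mu, sigma) such that the integer score distribution has the
    target mean and SD.  sigma here is the *total* latent spread, including
    any per-message noise."""
    if target_sd < 1e-9:
        return float(target_mean), 0.0

    def objective(x):
        mu, log_sigma = x
        m, s = _integer_score_moments(mu, math.exp(log_sigma))
        return [m - target_mean, s - target_sd]

    sol = root(objective, x0=[target_mean, math.log(target_sd)], method="hybr")
    if not sol.success:  # pragma: no cover - defensive; table values all solve
        raise GeneratorConfigError(
            f"no latent Normal yields integer-score mean {target_mean}, sd {target_sd}"
        )
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _endpoint_params(lv: EmotionLevels, noise_sd: float) -> tuple[float, float, float, float]:
    """(mu_begin, level_sd_begin, mu_end, level_sd_end): the latent *level*
    spread is the calibrated total spread with the message noise removed in
    quadrature (floored at 0 if the noise already exceeds it)."""
    mu_b, sig_b = latent_score_params(lv.begin_mean, lv.begin_sd)
    mu_e, sig_e = latent_score_params(lv.end_mean, lv.end_sd)
    s_b = math.sqrt(max(sig_b**2 - noise_sd**2, 0.0))
    s_e = math.sqrt(max(sig_e**2 - noise_sd**2, 0.0))
    return mu_b, s_b, mu_e, s_e


# ---------------------------------------------------------------------------
# Sampling primitives

def sample_latency(
    kind: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    size: Optional[int] = None,
) -> float | np.ndarray:
    """Strictly positive latency draw(s).

    Default is a lognormal moment-matched to the configured (mean, sd) --
    the reported SDs exceed the means, ruling out an untruncated normal.
    A zero-truncated normal (not moment-matched) is available via
    ``latency_distribution = "truncnorm"``.
    """
    try:
        spec = config.latency[kind]
    except KeyError:
        raise KeyError(f"unknown latency kind {kind!r}") from None
    if spec.sd <= 1e-12 * spec.mean:
        return spec.mean if size is None else np.full(size, spec.mean)
    if config.latency_distribution == "truncnorm":
        a = (0.0 - spec.mean) / spec.sd
        return truncnorm.rvs(a, np.inf, loc=spec.mean, scale=spec.sd, size=size, random_state=rng)
    sigma2 = math.log1p((spec.sd / spec.mean) ** 2)
    mu = math.log(spec.mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def simulate_emotion_series(
    group: str,
    emotion: str,
    m: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[Optional[int]]:
    """One user-visit's scores for one emotion over ``m`` messages.

    The latent level moves linearly from a sampled begin level to a sampled
    end level; each message adds Normal noise, is clipped to [1, 10],
    rounded to an integer, and dropped (None) with ``p_absent``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    em = config.emotion_model
    lv = em.levels[group][emotion]
    mu_b, s_b, mu_e, s_e = _endpoint_params(lv, em.noise_sd)
    b = mu_b + s_b * rng.standard_normal()
    e = mu_e + s_e * rng.standard_normal()
    frac = np.linspace(0.0, 1.0, m) if m > 1 else np.zeros(1)
    x = b + (e - b) * frac + em.noise_sd * rng.standard_normal(m)
    scores = np.rint(np.clip(x, 1.0, 10.0)).astype(int)
    present = rng.random(m) >= em.p_absent
    return [int(s) if p else None for s, p in zip(scores, present)]


def _emotion_matrix(
    mu_b: np.ndarray,
    s_b: np.ndarray,
    mu_e: np.ndarray,
    s_e: np.ndarray,
    noise_sd: float,
    p_absent: float,
    m: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(scores, present) of shape (m, n_emotions) for one visit."""
    k = len(mu_b)
    b = mu_b + s_b * rng.standard_normal(k)
    e = mu_e + s_e * rng.standard_normal(k)
    frac = (np.linspace(0.0, 1.0, m) if m > 1 else np.zeros(1))[:, None]
    x = b[None, :] + (e - b)[None, :] * frac + noise_sd * rng.standard_normal((m, k))
    scores = np.rint(np.clip(x, 1.0, 10.0)).astype(int)
    present = rng.random((m, k)) >= p_absent
    return scores, present


# ---------------------------------------------------------------------------
# Corpus generation

def _group_of(si_label: str, is_discloser: bool) -> str:
    if si_label == "none":
        return "non_exposed_non_si"
    if is_discloser:
        return f"{si_label}_si"
    return "exposed_non_si"


def _demo_key(group: str) -> str:
    return {"passive_si": "passive", "active_si": "active"}.get(group, "none")


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Draw a full corpus; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    em = config.emotion_model

    # Pre-resolve calibrated latent endpoint parameters per group x emotion.
    endpoint: dict[str, tuple[np.ndarray, ...]] = {}
    for group, levels in em.levels.items():
        cols = [_endpoint_params(levels[e], em.noise_sd) for e in EMOTIONS]
        endpoint[group] = tuple(np.array(c) for c in zip(*cols))

    topic_names = sorted(config.topics)
    topic_p = np.array([config.topics[t] for t in topic_names])
    upi_vals = np.array(sorted(config.users_per_session))
    upi_p = np.array([config.users_per_session[int(u)] for u in upi_vals])
    vocab = np.array(config.filler_vocab)
    lex_phrases = {
        cls: np.array([p for p, _ in lex]) for cls, lex in config.lexicons.items()
    }
    lex_p = {
        cls: np.array([w for _, w in lex], dtype=float) / sum(w for _, w in lex)
        for cls, lex in config.lexicons.items()
    }
    monthly_p = (
        np.asarray(config.monthly_weights, dtype=float) / sum(config.monthly_weights)
        if config.monthly_weights is not None
        else np.full(12, 1 / 12)
    )
    dm = config.demographics
    age_shape = ((dm.age_mean - dm.age_offset) / dm.age_sd) ** 2
    age_scale = dm.age_sd**2 / (dm.age_mean - dm.age_offset)
    gender_cats = {k: (np.array(sorted(v)), _normed(v)) for k, v in dm.gender.items()}
    race_cats = {k: (np.array(sorted(v)), _normed(v)) for k, v in dm.race.items()}

    sessions: list[ChatSession] = []
    visits: list[UserVisit] = []

    for i in range(config.n_sessions):
        sid = f"s{i:06d}"
        month = int(rng.choice(12, p=monthly_p)) + 1
        topic = topic_names[int(rng.choice(len(topic_names), p=topic_p))]
        u = int(rng.choice(upi_vals, p=upi_p))

        r = rng.random()
        if r < u * config.prevalence_passive:
            si_label = "passive"
        elif r < u * (config.prevalence_passive + config.prevalence_active):
            si_label = "active"
        else:
            si_label = "none"
        disc = int(rng.integers(0, u)) if si_label != "none" else -1

        m_per_user = config.messages_per_user_min + rng.poisson(
            config.messages_per_user_extra_mean, size=u
        )
        M = int(m_per_user.sum())
        slots = np.repeat(np.arange(u), m_per_user)
        rng.shuffle(slots)
        times = np.cumsum(rng.exponential(config.inter_message_mean_s, size=M))

        # Per-visit emotion score matrices.
        user_ids = [f"{sid}_u{j}" for j in range(u)]
        groups = [_group_of(si_label, j == disc) for j in range(u)]
        score_mats = []
        for j in range(u):
            mu_b, s_b, mu_e, s_e = endpoint[groups[j]]
            score_mats.append(
                _emotion_matrix(
                    mu_b, s_b, mu_e, s_e, em.noise_sd, em.p_absent, int(m_per_user[j]), rng
                )
            )

        # Text: filler tokens in bulk; disclosers embed a lexicon phrase.
        lengths = rng.integers(3, 9, size=M)
        tok_idx = rng.integers(0, len(vocab), size=int(lengths.sum()))
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        if si_label != "none":
            n_disc_msgs = int(m_per_user[disc])
            phrase_idx = rng.choice(
                len(lex_phrases[si_label]), size=n_disc_msgs, p=lex_p[si_label]
            )
        msgs: list[Message] = [
            Message(sid, MODERATOR_ID, "moderator", 0.0, 0, "welcome to the room", {})
        ]
        counters = [0] * u
        disc_first_t: Optional[float] = None
        for pos in range(M):
            j = int(slots[pos])
            k = counters[j]
            counters[j] += 1
            scores, present = score_mats[j]
            emotions = {
                EMOTIONS[c]: int(scores[k, c]) for c in range(len(EMOTIONS)) if present[k, c]
            }
            words = " ".join(vocab[tok_idx[offsets[pos] : offsets[pos + 1]]])
            if j == disc and si_label != "none":
                words = f"{lex_phrases[si_label][phrase_idx[k]]} {words}"
                if disc_first_t is None:
                    disc_first_t = float(times[pos])
            msgs.append(
                Message(sid, user_ids[j], "participant", float(times[pos]), pos + 1, words, emotions)
            )

        # Flag events.
        flags: list[FlagEvent] = []
        fm = config.flag_model
        if si_label != "none":
            t_lex = disc_first_t if disc_first_t is not None else float(times[0])
            has_ai = rng.random() < fm.p_ai_flag_given_si
            has_mod = si_label == "active" or rng.random() < fm.p_moderator_flag_given_si
            p_first = (
                config.ordering.p_ai_first_active
                if si_label == "active"
                else config.ordering.p_ai_first_passive
            )
            if has_ai:
                t_ai = t_lex
                flags.append(FlagEvent("ai", "crisis_flag", t_ai))
                if has_mod:
                    if rng.random() < p_first:
                        t2 = t_ai + float(sample_latency(si_label, config, rng))
                    else:
                        # moderator first: T2 = T1 - latency, resampled until positive
                        for _ in range(1000):
                            lat = float(sample_latency(si_label, config, rng))
                            if t_ai - lat > 0:
                                t2 = t_ai - lat
                                break
                        else:
                            t2 = t_ai * rng.random()
            elif has_mod:
                t2 = t_lex + float(sample_latency(si_label, config, rng))
            if has_mod:
                flags.append(FlagEvent("moderator", "protocol_question", t2))
                if si_label == "active":
                    t_last_q = t2
                    if rng.random() < config.p_safety_question:
                        t_last_q = t2 + float(rng.exponential(20.0))
                        flags.append(FlagEvent("moderator", "safety_question", t_last_q))
                    flags.append(
                        FlagEvent(
                            "moderator",
                            "referral",
                            t_last_q + float(sample_latency("referral", config, rng)),
                        )
                    )
        else:
            if rng.random() < fm.p_ai_flag_given_no_si:
                t_ai = float(times[int(rng.integers(0, M))])
                flags.append(FlagEvent("ai", "crisis_flag", t_ai))
        flags.sort(key=lambda ev: (ev.t, ev.source, ev.kind))

        sessions.append(
            ChatSession(
                session_id=sid,
                month=month,
                messages=msgs,
                si_label=si_label,
                si_discloser=user_ids[disc] if si_label != "none" else None,
                topic=topic,
                flags=flags,
            )
        )

        for j in range(u):
            demo = None
            if rng.random() < dm.p_disclose:
                key = _demo_key(groups[j])
                g_names, g_p = gender_cats[key]
                r_names, r_p = race_cats[key]
                demo = {
                    "gender": str(g_names[int(rng.choice(len(g_names), p=g_p))]),
                    "race": str(r_names[int(rng.choice(len(r_names), p=r_p))]),
                    "age": int(dm.age_offset + round(rng.gamma(age_shape, age_scale))),
                }
            visits.append(UserVisit(user_ids[j], sid, groups[j], demo))

    return Corpus(sessions=sessions, visits=visits)


def _normed(d: dict[str, float]) -> np.ndarray:
    names = sorted(d)
    p = np.array([d[k] for k in names], dtype=float)
    return p / p.sum()


# ---------------------------------------------------------------------------
# Config (de)serialization for YAML/CLI use

def config_to_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["lexicons"] = {
        cls: [[p, w] for p, w in lex] for cls, lex in config.lexicons.items()
    }
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "flag_model" in d and isinstance(d["flag_model"], dict):
        d["flag_model"] = FlagModel(**d["flag_model"])
    if "ordering" in d and isinstance(d["ordering"], dict):
        d["ordering"] = OrderingModel(**d["ordering"])
    if "latency" in d and isinstance(d["latency"], dict):
        d["latency"] = {
            k: v if isinstance(v, LatencySpec) else LatencySpec(**v)
            for k, v in d["latency"].items()
        }
    if "emotion_model" in d and isinstance(d["emotion_model"], dict):
        emd = dict(d["emotion_model"])
        if "levels" in emd:
            emd["levels"] = {
                g: {
                    e: lv if isinstance(lv, EmotionLevels) else EmotionLevels(**lv)
                    for e, lv in levels.items()
                }
                for g, levels in emd["levels"].items()
            }
        d["emotion_model"] = EmotionModel(**emd)
    if "demographics" in d and isinstance(d["demographics"], dict):
        d["demographics"] = DemographicsModel(**d["demographics"])
    if "users_per_session" in d:
        d["users_per_session"] = {int(k): float(v) for k, v in d["users_per_session"].items()}
    if "lexicons" in d:
        d["lexicons"] = {
            cls: [(str(p), float(w)) for p, w in lex] for cls, lex in d["lexicons"].items()
        }
    return GeneratorConfig(**d)
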