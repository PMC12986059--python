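# Methods

## Scope and model

The package evaluates a hybrid crisis-detection workflow on corpora of
moderated small-group chat sessions and analyzes users' emotional
trajectories within a session. The benchmark truth for detection is the
human moderator's protocol initiation (the scripted risk-assessment
question), not a session label: a session's confusion cell depends only on
which of the two flag streams (AI crisis flag, moderator protocol
question) are present, never on message content or flag order. An AI flag
raised *after* the moderator's question still counts as agreement; order
affects only the latency statistics.

Two latency quantities are distinguished deliberately:

- the **signed flag difference** T2 − T1 over all sessions with both flags
  (negative = moderator first), whose mean/SD and AI-first share
  (`p_ai_first`) describe the full timing distribution; and
- the **follow-up latency**, the mean of T2 − T1 over the AI-first subset
  only — "how long after the AI alert did the moderator act". The headline
  ~71 s (active) / ~80 s (passive) figures are follow-up latencies; the
  signed mean is necessarily smaller because moderator-first sessions
  contribute negative terms. `LatencyStats` reports both so neither is
  conflated with the other.

Referral timeliness is the delay from the moderator's *last*
crisis-determination question (protocol or the 24-hour safety commitment
question, whichever came later) to the referral event, over active-SI
sessions.

## Synthetic generator

The generator emulates the statistical structure the analyses assume; it
is the package's data source and its defaults are the study conditions.

**Session structure.** Sessions hold 1–5 user visits (default mix with
mean 2.7), each contributing 3 + Poisson(5) messages (so every generated
session passes the ≥ 3-messages inclusion rule), interleaved in random
order with exponential inter-message gaps (mean 30 s). Message counts and
pacing are not reported for the real service; these defaults are explicit,
configurable placeholders.

**SI assignment.** Per-visit prevalence is the primitive (defaults 0.0198
passive, 0.0121 active). A session of u users discloses passive SI with
probability u·0.0198 and active with u·0.0121, with one uniformly chosen
discloser — so the *per-visit* discloser rate equals the configured
prevalence exactly, whatever the group-size mix. Validation rejects
configurations where u_max·(p_passive + p_active) exceeds 1. Other visits
in SI sessions are "exposed"; visits in SI-free sessions are "non-exposed".

**Flags and latencies.** The moderator flags every SI session (the labels
are moderator-defined); the AI flags SI sessions with probability 0.8751
(its sensitivity against the benchmark) and SI-free sessions with
probability 14 735/155 401 (the false-positive rate). The AI flag sits at
the discloser's first message; with the configured AI-first probability
(0.8126 active / 0.7752 passive) the protocol question follows the AI flag
by a latency draw, otherwise it precedes it by one (redrawn until the
protocol time stays positive, capped at 1000 attempts with a uniform
fallback), so the AI-first share is honored by construction. Latencies are
lognormal, moment-matched to the configured (mean, SD) — the SDs exceed
the means, which rules out an untruncated normal and indicates strong
right skew; a zero-truncated normal is available via
`latency_distribution = "truncnorm"` as a lighter-tailed alternative (not
moment-matched). Active sessions append an optional safety question
(probability 0.5, exponential 20 s gap — arbitrary, configurable) and a
referral at the last question plus a lognormal(245, 557) s delay.

**Emotion scores.** Each visit's latent emotion level moves linearly from
a sampled begin level to a sampled end level; each message adds Normal
noise (SD 0.4), is clipped to [1, 10], rounded to an integer, and dropped
with probability 0.2 ("not detected"). Group defaults come from the
reported begin/end means and SDs per group and emotion; active-SI visits
reuse the passive profile since no levels are reported for them (they are
excluded from trajectory analyses anyway).

*Calibration.* Clipping and rounding bias the realized moments of a
naively parameterized Normal: an end level of 3.74 with SD 2.19 has ~10%
of its mass below the floor, inflating the realized mean by ≈ 0.11 — an
order of magnitude larger than the Monte-Carlo error the recovery tests
allow. The generator therefore solves, per (mean, SD) target, for the
latent (μ, σ) such that the *integer score distribution*
P(k) = Φ((k+½−μ)/σ) − Φ((k−½−μ)/σ) (with the boundary cells absorbing the
tails) has exactly the target mean and SD (2-D root find, cached). The
per-message noise is removed from σ in quadrature to get the between-visit
level spread; the default noise SD (0.4) is kept below the smallest
calibrated σ (≈ 0.5, optimism begin) so that spread stays positive.

**Text.** Discloser messages embed one lexicon phrase, drawn with
probability proportional to the configured phrase frequencies, among
neutral filler tokens; other messages are filler only. The filler
vocabulary is ~130 distinct common words, so individual filler words recur
rarely within a session and embedded SI phrases are distinctive against
the background — the property the phrase-ranking analysis relies on. Text
realism ends there by design: no language model is involved.

**Demographics.** Disclosure is Bernoulli(0.30), independent of group (a
simplifying default; dependence is unknown). Gender and race mixes are
per-group categorical draws; age is 13 + Gamma moment-matched to mean 24 /
SD 12 — an acknowledged approximation that reproduces scale and skew, not
the exact reported median.

**Determinism.** One `numpy` Generator seeded from the config drives all
sampling in a fixed order; identical config + seed yields byte-identical
serialized corpora.

## Trajectory analysis

Scored messages (absent scores skipped) are knots at i/(m−1); curves are
piecewise linear (`numpy.interp`) on a 101-point grid (0%, 1%, …, 100%) —
fine enough to represent linear segments exactly while keeping the ANCOVA
design small. Knots are placed by scored-message *index*, matching the
"normalized message progression" covariate; wall-clock placement was
considered and rejected as the default because pacing is uninformative
filler in the generator. Visits with fewer than two scored messages are
skipped with a logged reason. Percent change is (begin − end)/begin for
the negative emotions (a reduction) and (end − begin)/begin for optimism
(an increase), evaluated on the aggregate curve's endpoints.

Eligibility requires a score ≥ 5 within the focal user's first three
messages (conversations must begin with measurable distress); active-SI
visits are always excluded. For optimism the threshold cannot apply to the
analyzed emotion itself (optimism begins near 2 by design, so the subset
would be empty); the pipeline gates optimism analyses on the four negative
emotions instead, via the `threshold_emotions` parameter. For SI groups
the discloser is the focal user; for exposure groups each exposed visit is
its own focal user while the discloser defines the session's exposure
status.

## Matching

Propensities come from a logistic regression of treatment on initial
intensity (max score over the focal user's first three gate-emotion
messages) and topic (one-hot, most frequent level dropped for a
deterministic reference), fit by IRLS to gradient max-norm < 1e-8 or 100
iterations. Perfect separation is detected (fitted probabilities
saturating at the labels, divergent coefficients, or a singular system)
and raised with advice to enable the ridge penalty (L2 on non-intercept
terms, 1e-6 when enabled). One propensity model is fit per comparison ×
emotion — per-analysis rather than global, since each analysis has its own
eligible subset; the alternative is a config choice away.

Matching is greedy 1:1 nearest-neighbor without replacement on |logit
difference|, with propensities clipped to [1e-12, 1 − 1e-12] before the
logit so saturated fits cannot produce infinities. Treated units are
processed in a seeded random permutation (the processing order is
otherwise an arbitrary systematic choice); equally distant controls
tie-break to the lowest unit id. Pairs farther than the caliper (0.01
logit units) are excluded, and the caliper bound is asserted on every run.
Balance is summarized by the standardized mean difference per covariate,
using the pre-matching pooled SD in both columns.

## Statistics

**Mann–Whitney U** uses midranks; U_a + U_b = n_a·n_b always. For samples
without ties and n_a·n_b ≤ 200 the two-sided p comes from the exact null
distribution of the rank sum (counting recurrence); the exact-with-ties
distribution is not implemented, so tied samples use the normal
approximation with tie-corrected variance and a 0.5 continuity correction
even below the product threshold. The integer 1–10 scale means real
baseline comparisons essentially always take the tie-corrected normal
path; the exact path matters for small simulations and is cross-checked
against an independent implementation in the tests.

**ANCOVA** is OLS of score on {1, time, group, group×time}; the
interaction p uses the t distribution with n − 4 df. Input points are each
matched visit's interpolated grid values, so every conversation
contributes equally many points and long chats do not dominate; a
raw-message alternative would weight by verbosity and is deliberately not
the default. Residual dependence within a session is ignored by default (a
cluster-robust covariance is available via `cluster_by_session=True`);
with grid-resampled points the default materially understates standard
errors when within-session correlation is strong, which is a known
limitation of the mirrored procedure rather than of the implementation.

**Phrase ranking** defaults to top-1 per message under the
term-frequency cosine ranker: for equally frequent tokens the cosine grows
with the square root of phrase length, so the full embedded phrase
outranks its own sub-windows and the frequency table recovers whole
phrases rather than fragments. The ranker sits behind a one-method
interface (`score(phrase, context)`) so a sentence-embedding model can be
swapped in without touching the pipeline.

## Problem sizes and tolerances

Monte-Carlo recovery tests use preregistered 3-standard-error bands at
fixed seeds. The shared test corpora are 20 000 sessions at default
prevalence (prevalence, demographics, baseline levels) and 10 000 sessions
at 9%/9% per-visit prevalence (latency, ordering, referral, sensitivity:
~2 500 sessions per SI class); the acceptance script uses 42 000 sessions
at 9%/9% (~10 200 per class). The ANCOVA type-I simulation runs 500 null
replicates of 400 sessions × 5 grid points. These sizes were chosen so
every 3-SE band is a few percent of the target or less while the full
suite stays interactive.

## What passing tests do and do not show

The generator reproduces the *marginal* structure the analyses consume:
prevalences, flag agreement and ordering, latency moments, begin/end score
distributions, lexicon frequencies, disclosure rates. It does not model
conversational dynamics (turn-taking, moderator interventions affecting
trajectories), dependence between emotions within a message, non-linear or
non-monotone emotional arcs beyond additive noise, repeat visits by the
same individual, or any dependence of disclosure on group. Passing
recovery tests therefore demonstrates that the estimators are correct and
well-calibrated on data satisfying the stated assumptions — not that real
crisis conversations satisfy them. In particular, matched-cohort percent
changes computed on eligibility-filtered synthetic subsets are expected to
differ from published cohort figures, whose exact denominators are not
reconstructible from summary tables; those figures are treated as
out of reach of desk-scale reproduction, and the pipeline's correctness is
instead established by exact noiseless recovery, oracle agreement and
invariant checks.
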