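"""End-to-end analysis pipeline: configuration, seeding, and the report
bundle chaining every stage (detection evaluation, prevalence,
demographics, phrase tables, eligibility, matching, trajectories, ANCOVA).

A single pipeline seed fans out to per-stage child seeds by stable hashing
of the stage name, so adding a stage never perturbs another stage's
randomness.  Outputs carry no timestamps and serialize with sorted keys,
so identical config + seed produces byte-identical, checksummable files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .detection import (
    confusion_counts,
    detection_metrics,
    flag_latency_stats,
    prevalence_summary,
    referral_latency_stats,
)
from .group_stats import ancova_interaction, baseline_comparison
from .matching import MatchRecord, MatchResult, fit_propensity, match_pairs, standardized_mean_diff
from .ngrams import phrase_frequency_table
from .synthetic import GeneratorConfig, generate_corpus
from .trajectory import (
    DEFAULT_GRID_POINTS,
    aggregate_trajectories,
    eligible_visits,
    percent_change,
    trajectory_curves,
)
from .transcript import (
    Corpus,
    EMOTIONS,
    NEGATIVE_EMOTIONS,
    read_corpus,
    summarize_demographics,
    validate_corpus,
    write_corpus,
)

logger = logging.getLogger(__name__)

DEFAULT_COMPARISONS: tuple[tuple[str, str, str], ...] = (
    ("passive-vs-none", "passive_si", "non_exposed_non_si"),
    ("exposed-vs-nonexposed", "exposed_non_si", "non_exposed_non_si"),
)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived by hashing the stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class AnalysisConfig:
    generator: Optional[GeneratorConfig] = None
    corpus_path: Optional[str] = None
    comparisons: Sequence[tuple[str, str, str]] = DEFAULT_COMPARISONS
    emotions: Sequence[str] = EMOTIONS
    threshold: int = 5
    window: int = 3
    grid_points: int = DEFAULT_GRID_POINTS
    caliper: float = 0.01
    min_freq: int = 2
    baseline_min_messages: int = 5
    seed: int = 0
    out_dir: str = "results/run"

    def __post_init__(self):
        if self.generator is None and self.corpus_path is None:
            self.generator = GeneratorConfig(seed=self.seed)


def initial_intensity(
    session, user_id: str, emotions: Sequence[str], window: int
) -> Optional[float]:
    """Matching covariate: max score over the focal user's first ``window``
    messages across the given emotions; None if no score is present."""
    first = session.participant_messages(user_id)[:window]
    scores = [m.emotions[e] for m in first for e in emotions if e in m.emotions]
    return float(max(scores)) if scores else None


@dataclass
class ComparisonResult:
    name: str
    emotion: str
    treated_group: str
    control_group: str
    n_eligible_treated: int
    n_eligible_control: int
    match: MatchResult
    balance: list
    treated_curve: object
    control_curve: object
    treated_pct_change: float
    control_pct_change: float
    ancova: object
    baseline: object


def run_comparison(
    corpus: Corpus,
    emotion: str,
    treated_group: str,
    control_group: str,
    *,
    name: str = "",
    threshold: int = 5,
    window: int = 3,
    grid_points: int = DEFAULT_GRID_POINTS,
    caliper: float = 0.01,
    baseline_min_messages: int = 5,
    seed: int = 0,
    threshold_emotions: Optional[Sequence[str]] = None,
) -> ComparisonResult:
    """Eligibility -> propensity matching -> matched trajectories -> ANCOVA
    for one emotion and one treated/control group pair.

    Optimism conversations gate eligibility on the negative emotions (a
    conversation "begins with measurable distress" when any negative
    emotion reaches the threshold), since optimism starts low by design.
    """
    if threshold_emotions is None:
        threshold_emotions = (emotion,) if emotion != "optimism" else NEGATIVE_EMOTIONS
    sessions = corpus.session_by_id()

    records: list[MatchRecord] = []
    pair_of: dict[str, tuple[str, str]] = {}
    counts = {}
    for treated, group in ((True, treated_group), (False, control_group)):
        pairs = eligible_visits(
            corpus,
            emotion,
            group=group,
            threshold=threshold,
            window=window,
            threshold_emotions=threshold_emotions,
        )
        counts[treated] = len(pairs)
        for sid, uid in pairs:
            intensity = initial_intensity(sessions[sid], uid, threshold_emotions, window)
            if intensity is None:
                continue
            rid = f"{sid}:{uid}"
            records.append(
                MatchRecord(
                    id=rid,
                    treated=treated,
                    initial_intensity=intensity,
                    topic=sessions[sid].topic,
                )
            )
            pair_of[rid] = (sid, uid)

    propensities = fit_propensity(records)
    match = match_pairs(records, propensities, caliper=caliper, rng=seed)
    balance = standardized_mean_diff(records, match) if match.pairs else []

    treated_pairs = [pair_of[t] for t, _, _ in match.pairs]
    control_pairs = [pair_of[c] for _, c, _ in match.pairs]
    t_curves, _ = trajectory_curves(corpus, treated_pairs, emotion, grid_points)
    c_curves, _ = trajectory_curves(corpus, control_pairs, emotion, grid_points)
    if not t_curves or not c_curves:
        raise ValueError(
            f"comparison {name or emotion!r}: no matched trajectories "
            f"({len(t_curves)} treated, {len(c_curves)} control curves)"
        )
    t_agg = aggregate_trajectories(t_curves, emotion)
    c_agg = aggregate_trajectories(c_curves, emotion)

    grid = np.linspace(0.0, 1.0, grid_points)
    frames = []
    for g, curves, pairs in ((1, t_curves, treated_pairs), (0, c_curves, control_pairs)):
        for (sid, uid), curve in zip(pairs, curves):
            frames.append(
                pd.DataFrame(
                    {"session_id": f"{sid}:{uid}", "group": g, "time": grid, "score": curve}
                )
            )
    points = pd.concat(frames, ignore_index=True)
    ancova = ancova_interaction(points)

    baseline = baseline_comparison(
        corpus, emotion, (treated_group, control_group), min_messages=baseline_min_messages
    )

    return ComparisonResult(
        name=name or f"{treated_group}-vs-{control_group}",
        emotion=emotion,
        treated_group=treated_group,
        control_group=control_group,
        n_eligible_treated=counts[True],
        n_eligible_control=counts[False],
        match=match,
        balance=balance,
        treated_curve=t_agg,
        control_curve=c_agg,
        treated_pct_change=percent_change(t_agg, emotion),
        control_pct_change=percent_change(c_agg, emotion),
        ancova=ancova,
        baseline=baseline,
    )


# ---------------------------------------------------------------------------
# Report bundle

def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _latency_dict(stats) -> dict:
    return {
        "n": stats.n,
        "mean_s": stats.mean,
        "sd_s": stats.sd,
        "p_ai_first": stats.p_ai_first,
        "follow_up_n": stats.follow_up_n,
        "follow_up_mean_s": stats.follow_up_mean,
        "follow_up_sd_s": stats.follow_up_sd,
    }


def run_analysis(config: AnalysisConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns the manifest (also written as ``manifest.json``), which records
    the config hash, the seed, per-file checksums, and per-stage record
    counts into and out of every filter for auditability.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "files": {},
        "stages": {},
        "complete": False,
    }
    stage = "setup"
    try:
        stage = "corpus"
        if config.corpus_path is not None:
            corpus = read_corpus(config.corpus_path)
        else:
            corpus = generate_corpus(config.generator)
            write_corpus(corpus, out / "corpus.jsonl")
        violations = validate_corpus(corpus)
        if violations:
            raise ValueError(f"corpus invalid: {violations[:3]}")
        manifest["stages"]["corpus"] = {
            "n_sessions": len(corpus.sessions),
            "n_visits": len(corpus.visits),
        }
        logger.info("corpus: %d sessions, %d visits", len(corpus.sessions), len(corpus.visits))

        gen_cfg = config.generator
        cfg_repr = {
            "generator": None if gen_cfg is None else _stable_config_dict(gen_cfg),
            "corpus_path": config.corpus_path,
            "comparisons": list(map(list, config.comparisons)),
            "emotions": list(config.emotions),
            "threshold": config.threshold,
            "window": config.window,
            "grid_points": config.grid_points,
            "caliper": config.caliper,
            "min_freq": config.min_freq,
            "baseline_min_messages": config.baseline_min_messages,
            "seed": config.seed,
        }
        manifest["config_sha256"] = hashlib.sha256(
            json.dumps(cfg_repr, sort_keys=True).encode()
        ).hexdigest()

        stage = "detection"
        counts = confusion_counts(corpus)
        metrics = detection_metrics(counts)
        detection_report = {
            "confusion": {"tp": counts.tp, "fp": counts.fp, "fn": counts.fn, "tn": counts.tn},
            "metrics_fraction": {
                k: getattr(metrics, k)
                for k in ("sensitivity", "specificity", "precision", "npv", "accuracy")
            },
            "metrics_percent": metrics.as_percentages(),
            "flag_latency": {
                cls: _latency_dict(flag_latency_stats(corpus, cls))
                for cls in ("passive", "active")
            },
            "referral_latency": {
                k: v
                for k, v in _latency_dict(referral_latency_stats(corpus)).items()
                if not k.startswith(("p_ai", "follow"))
            },
        }
        _json_dump(detection_report, out / "detection.json")

        stage = "prevalence"
        prev = prevalence_summary(corpus)
        _json_dump(
            {
                "n_visits": prev.n_visits,
                "n_sessions": prev.n_sessions,
                "passive_visits": prev.passive_visits,
                "active_visits": prev.active_visits,
                "rates_percent": {
                    "passive_of_visits": prev.passive_rate_visits * 100,
                    "active_of_visits": prev.active_rate_visits * 100,
                    "passive_of_sessions": prev.passive_rate_sessions * 100,
                    "active_of_sessions": prev.active_rate_sessions * 100,
                    "exposure_of_visits": prev.exposure_rate * 100,
                },
                "passive_active_ratio": prev.ratio_label(),
                "monthly": {
                    "passive": prev.monthly_passive,
                    "active": prev.monthly_active,
                    "sessions": prev.monthly_sessions,
                },
            },
            out / "prevalence.json",
        )

        stage = "demographics"
        demo = summarize_demographics(corpus.visits, by_group=True)
        _json_dump(
            {
                g: {
                    "n_visits": d.n_visits,
                    "non_disclosure_rate": d.non_disclosure_rate,
                    "categories": d.categories,
                    "age": d.age,
                }
                for g, d in demo.items()
            },
            out / "demographics.json",
        )

        stage = "phrases"
        for cls in ("active", "passive"):
            table = phrase_frequency_table(corpus.sessions, cls, min_freq=config.min_freq)
            pd.DataFrame(table.rows, columns=["phrase", "frequency"]).to_csv(
                out / f"phrases_{cls}.csv", index=False
            )
            manifest["stages"][f"phrases_{cls}"] = {"n_rows": len(table.rows)}

        stage = "comparisons"
        comp_report = {}
        for name, treated, control in config.comparisons:
            for emotion in config.emotions:
                cstage = f"{name}/{emotion}"
                try:
                    res = run_comparison(
                        corpus,
                        emotion,
                        treated,
                        control,
                        name=name,
                        threshold=config.threshold,
                        window=config.window,
                        grid_points=config.grid_points,
                        caliper=config.caliper,
                        baseline_min_messages=config.baseline_min_messages,
                        seed=child_seed(config.seed, f"match:{cstage}"),
                    )
                except ValueError as exc:
                    logger.warning("comparison %s skipped: %s", cstage, exc)
                    comp_report[cstage] = {"skipped": str(exc)}
                    continue
                comp_report[cstage] = {
                    "n_eligible": {
                        "treated": res.n_eligible_treated,
                        "control": res.n_eligible_control,
                    },
                    "n_pairs": res.match.n_pairs,
                    "n_excluded": len(res.match.excluded),
                    "balance_smd": {
                        row.covariate: {"before": row.smd_before, "after": row.smd_after}
                        for row in res.balance
                    },
                    "pct_change": {
                        "treated": res.treated_pct_change,
                        "control": res.control_pct_change,
                    },
                    "ancova": {
                        "interaction": res.ancova.coefficients["group_time"],
                        "t": res.ancova.t_interaction,
                        "p": res.ancova.p_interaction,
                        "slopes": {str(k): v for k, v in res.ancova.slopes.items()},
                        "n_points": res.ancova.n_points,
                        "n_sessions": res.ancova.n_sessions,
                    },
                    "baseline": {
                        "treated": _baseline_dict(res.baseline.a),
                        "control": _baseline_dict(res.baseline.b),
                        "mann_whitney": {
                            "u": res.baseline.mann_whitney.u,
                            "z": res.baseline.mann_whitney.z,
                            "p": res.baseline.mann_whitney.p,
                            "method": res.baseline.mann_whitney.method,
                        },
                    },
                }
                pd.DataFrame(
                    {
                        "grid": res.treated_curve.grid,
                        "treated_mean": res.treated_curve.values,
                        "treated_sd": res.treated_curve.sd,
                        "control_mean": res.control_curve.values,
                        "control_sd": res.control_curve.sd,
                    }
                ).to_csv(out / f"trajectory_{name}_{emotion}.csv", index=False)
        _json_dump(comp_report, out / "comparisons.json")

        stage = "report"
        (out / "report.md").write_text(_markdown_report(detection_report, comp_report))
        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        _finalize_manifest(manifest, out)
        raise PipelineStageError(stage, exc) from exc

    _finalize_manifest(manifest, out)
    return manifest


def _baseline_dict(b) -> dict:
    return {
        "group": b.group,
        "n_begin": b.n_begin,
        "begin_mean": b.begin_mean,
        "begin_sd": b.begin_sd,
        "end_mean": b.end_mean,
        "end_sd": b.end_sd,
    }


def _stable_config_dict(cfg: GeneratorConfig) -> dict:
    from .synthetic import config_to_dict

    return json.loads(json.dumps(config_to_dict(cfg), sort_keys=True, default=str))


def _finalize_manifest(manifest: dict, out: Path) -> None:
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    _json_dump(manifest, out / "manifest.json")


def _markdown_report(detection: dict, comparisons: dict) -> str:
    lines = ["# Analysis report", "", "## Detection", ""]
    conf = detection["confusion"]
    lines.append(
        f"Confusion counts: TP {conf['tp']}, FP {conf['fp']}, FN {conf['fn']}, TN {conf['tn']}."
    )
    pct = detection["metrics_percent"]
    lines.append(
        "Metrics (%): "
        + ", ".join(f"{k} {v}" for k, v in sorted(pct.items()) if v is not None)
    )
    lines += ["", "## Matched comparisons", ""]
    lines.append("| comparison | pairs | pct change (T/C) | ANCOVA p |")
    lines.append("|---|---|---|---|")
    for name, rep in sorted(comparisons.items()):
        if "skipped" in rep:
            lines.append(f"| {name} | - | - | skipped |")
            continue
        pc = rep["pct_change"]
        lines.append(
            f"| {name} | {rep['n_pairs']} | {pc['treated']:.1f}% / {pc['control']:.1f}% "
            f"| {rep['ancova']['p']:.3f} |"
        )
    return "\n".join(lines) + "\n"
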