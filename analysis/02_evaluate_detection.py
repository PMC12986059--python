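#!/usr/bin/env python
"""Evaluate the hybrid AI/moderator crisis detection on the simulated
corpus: confusion counts against the moderator benchmark, the five
agreement metrics, flag follow-up latencies (T2 - T1), referral
timeliness, SI prevalence and demographic mix.

Reads results/corpus.jsonl (from 01_simulate_corpus.py) and writes
results/detection_eval.json.
"""

import json
from pathlib import Path

from crisischat.detection import (
    confusion_counts,
    detection_metrics,
    flag_latency_stats,
    prevalence_summary,
    referral_latency_stats,
)
from crisischat.pipeline import _latency_dict
from crisischat.transcript import read_corpus, summarize_demographics

OUT = Path("results")


def main() -> None:
    corpus = read_corpus(OUT / "corpus.jsonl")
    counts = confusion_counts(corpus)
    metrics = detection_metrics(counts).as_percentages()
    latency = {cls: flag_latency_stats(corpus, cls) for cls in ("active", "passive")}
    referral = referral_latency_stats(corpus)
    prev = prevalence_summary(corpus)
    demo = summarize_demographics(corpus.visits, by_group=True)

    print(f"confusion: TP {counts.tp} FP {counts.fp} FN {counts.fn} TN {counts.tn}")
    print("metrics (%):", {k: v for k, v in metrics.items()})
    for cls, st in latency.items():
        print(
            f"{cls}: follow-up {st.follow_up_mean:.1f} s (sd {st.follow_up_sd:.1f}) "
            f"over n={st.follow_up_n}; AI first in {st.p_ai_first:.1%} of {st.n} sessions"
        )
    print(f"referral delay: {referral.mean:.0f} s (sd {referral.sd:.0f}, n={referral.n})")
    print(
        f"prevalence per visit: passive {prev.passive_rate_visits:.2%}, "
        f"active {prev.active_rate_visits:.2%}, ratio {prev.ratio_label()}, "
        f"exposure {prev.exposure_rate:.2%}"
    )

    report = {
        "confusion": {"tp": counts.tp, "fp": counts.fp, "fn": counts.fn, "tn": counts.tn},
        "metrics_percent": metrics,
        "flag_latency": {cls: _latency_dict(st) for cls, st in latency.items()},
        "referral_latency": _latency_dict(referral),
        "prevalence_percent": {
            "passive_of_visits": prev.passive_rate_visits * 100,
            "active_of_visits": prev.active_rate_visits * 100,
            "exposure_of_visits": prev.exposure_rate * 100,
        },
        "passive_active_ratio": prev.ratio_label(),
        "monthly_si_sessions": {
            "passive": prev.monthly_passive,
            "active": prev.monthly_active,
        },
        "demographics": {
            g: {
                "non_disclosure_rate": d.non_disclosure_rate,
                "gender": d.categories["gender"],
                "age": d.age,
            }
            for g, d in demo.items()
        },
    }
    (OUT / "detection_eval.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    print(f"-> {OUT/'detection_eval.json'}")


if __name__ == "__main__":
    main()
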