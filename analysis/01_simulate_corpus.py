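#!/usr/bin/env python
"""Simulate a year-like corpus of moderated group chats under the default
study conditions (1.98%/1.21% per-visit SI prevalence, calibrated flag and
latency models, per-group emotion levels) and write it to
results/corpus.jsonl for the downstream analysis steps.

8,000 sessions keeps every later step interactive while leaving a few
hundred SI sessions for the detection and phrase analyses.
"""

from pathlib import Path

from crisischat.synthetic import GeneratorConfig, generate_corpus
from crisischat.transcript import validate_corpus, write_corpus

OUT = Path("results")
SEED = 20240101


def main() -> None:
    OUT.mkdir(exist_ok=True)
    config = GeneratorConfig(n_sessions=8_000, seed=SEED)
    corpus = generate_corpus(config)
    violations = validate_corpus(corpus)
    assert not violations, violations[:3]

    n_passive = sum(s.si_label == "passive" for s in corpus.sessions)
    n_active = sum(s.si_label == "active" for s in corpus.sessions)
    write_corpus(corpus, OUT / "corpus.jsonl")
    print(
        f"wrote {len(corpus.sessions)} sessions / {len(corpus.visits)} visits "
        f"({n_passive} passive-SI, {n_active} active-SI sessions) -> {OUT/'corpus.jsonl'}"
    )


if __name__ == "__main__":
    main()
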