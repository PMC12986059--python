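#!/usr/bin/env python
"""Mine characteristic 2-5-token phrases from SI-discloser messages, per SI
class, using the term-frequency cosine ranker, and tabulate frequencies
(frequency > 1).  Active-SI language should surface explicit intent
("just wanna die") while passive-SI language surfaces despair and escape
("just feel lonely", "just wanna disappear").

Reads results/corpus.jsonl; writes results/phrases_{active,passive}.csv.
"""

from pathlib import Path

import pandas as pd

from crisischat.ngrams import phrase_frequency_table
from crisischat.transcript import read_corpus

OUT = Path("results")


def main() -> None:
    corpus = read_corpus(OUT / "corpus.jsonl")
    for cls in ("active", "passive"):
        table = phrase_frequency_table(corpus.sessions, cls, min_freq=2)
        pd.DataFrame(table.rows, columns=["phrase", "frequency"]).to_csv(
            OUT / f"phrases_{cls}.csv", index=False
        )
        print(f"{cls}: {len(table.rows)} phrases; top 5:")
        for phrase, freq in table.top(5):
            print(f"  {freq:5d}  {phrase}")


if __name__ == "__main__":
    main()
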