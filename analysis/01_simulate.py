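#!/usr/bin/env python
"""Generate the synthetic reading study.

A Zipfian corpus read by 20 native (L1) and 60 non-native (L2) participants in
an individual-materials regime. Generative reading times are linear in
surprisal (5 ms/bit), negative log-frequency (3 ms/bit) and word length
(2 ms/char), with previous-word spillover, participant random effects, and
amplitudes modulated by proficiency as an inverted U (so lower-proficiency L2
readers show larger effects, peaking mid-scale). Writes the raw study tables
under results/data/.
"""

import json
from pathlib import Path

import pandas as pd

from lexcontext.io import substream_seed, write_table
from lexcontext.synth import (
    GenerativeEffectSpec,
    SyntheticCorpusSpec,
    generate_dataset,
    measures_to_events,
)

SEED = 2026
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    corpus_spec = SyntheticCorpusSpec(
        vocab_size=2000, n_sentences=4000, sentence_length=(9, 16),
        seed=substream_seed(SEED, "corpus"),
    )
    effect_spec = GenerativeEffectSpec(
        effects={"surp": (5.0,), "freq": (3.0,), "len": (2.0,)},
        spillover={"surp": 1.0, "freq": 0.5, "len": 0.5},
        noise_sd=30.0,
        skip_prob=0.08,
        u_scale=0.5,  # proficiency-modulated amplitudes: U-shaped effect sizes
    )
    data = generate_dataset(
        corpus_spec,
        n_l1=20,
        n_l2=60,
        effect_spec=effect_spec,
        mpt_distribution=("uniform", (2, 50)),
        random_effect_sds={"intercept": 20.0, "surp": 0.3, "freq": 0.2, "len": 0.2},
        seed=substream_seed(SEED, "dataset"),
    )

    sentences = pd.DataFrame(
        [
            {"trial_id": tid, "word_index": i, "word": w}
            for tid, words in data["corpus"].sentences.items()
            for i, w in enumerate(words)
        ]
    )
    write_table(sentences, OUT / "sentences.csv", seed=SEED)
    data["corpus"].freq_table.to_tsv(OUT / "frequency.tsv")
    lm = data["corpus"].lm
    (OUT / "lm.json").write_text(
        json.dumps(
            {
                "words": lm.words,
                "probs": lm.p.tolist(),
                "graph_seed": corpus_spec.seed,
                "graph_degree": corpus_spec.graph_degree,
                "graph_weight": corpus_spec.graph_weight,
            }
        )
    )
    profiles = pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "group": p.group,
                "native_language": p.native_language,
                "mpt": p.mpt,
                "comprehension_accuracy": round(p.comprehension_accuracy, 6),
            }
            for p in data["profiles"]
        ]
    )
    write_table(profiles, OUT / "participants.csv", seed=SEED)
    write_table(data["annotations"].round(9), OUT / "annotations.csv", seed=SEED)
    events = measures_to_events(data["measures"])
    write_table(events, OUT / "events.csv", seed=SEED)
    # reference copy of the generative measures, for pipeline validation
    write_table(data["measures"], OUT / "measures_generative.csv", seed=SEED)

    n_l2 = (profiles["group"] == "L2").sum()
    print(f"corpus: {data['corpus'].n_tokens} tokens, {len(sentences['trial_id'].unique())} sentences")
    print(f"participants: {len(profiles)} ({n_l2} L2), MPT range "
          f"{profiles['mpt'].min()}-{profiles['mpt'].max()}")
    print(f"events: {len(events)} fixations -> {OUT}")


if __name__ == "__main__":
    main()
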