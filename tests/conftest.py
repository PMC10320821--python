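import numpy as np
import pandas as pd
import pytest

from lexcontext import annotate, synth


@pytest.fixture(scope="session")
def small_corpus():
    spec = synth.SyntheticCorpusSpec(
        vocab_size=400, n_sentences=300, sentence_length=(6, 14), seed=101
    )
    return synth.generate_corpus(spec)


@pytest.fixture(scope="session")
def small_annotations(small_corpus):
    return annotate.annotate_sentences(
        small_corpus.sentences, small_corpus.freq_table, small_corpus.lm
    )


@pytest.fixture(scope="session")
def small_profiles():
    return synth.generate_participants(
        4,
        8,
        mpt_distribution=("uniform", (5, 50)),
        random_effect_sds={"intercept": 15.0, "surp": 0.3, "freq": 0.2, "len": 0.2},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_measures(small_corpus, small_annotations, small_profiles):
    eff = synth.GenerativeEffectSpec()
    return synth.generate_reading_times(
        small_corpus, small_annotations, small_profiles, eff, seed=8
    )


@pytest.fixture(scope="session")
def small_retained(small_annotations, small_measures):
    retained, counts = annotate.apply_exclusions(small_annotations, small_measures)
    return retained


@pytest.fixture(scope="session")
def toy_bigram_sentences():
    """Tiny corpus for hand-checkable bigram surprisal values."""
    return [
        "the cat sat".split(),
        "the dog sat".split(),
        "the cat ran".split(),
        "a dog ran".split(),
        "the dog barked".split(),
        "a cat sat".split(),
        "the bird sang".split(),
        "a bird flew".split(),
        "the cat slept".split(),
        "the dog slept".split(),
        "a cat ran".split(),
        "the bird flew".split(),
    ]
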