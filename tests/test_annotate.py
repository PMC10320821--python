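import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexcontext.annotate import (
    BigramLM,
    FrequencyTable,
    ZeroProbabilityError,
    annotate_sentences,
    apply_exclusions,
    neg_log_frequency,
    surprisal,
    word_length,
)


class TestFrequencyTable:
    def test_total_is_sum_of_counts(self):
        t = FrequencyTable.from_pairs([("the", 6), ("cat", 2), ("sat", 2)])
        assert t.total == 10

    def test_duplicate_word_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            FrequencyTable.from_pairs([("cat", 2), ("cat", 3)])

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            FrequencyTable.from_pairs([("cat", 0)])

    def test_case_folded_lookup(self):
        t = FrequencyTable.from_pairs([("The", 4)])
        assert t.count("the") == 4 and t.count("THE") == 4

    def test_tsv_round_trip(self, tmp_path):
        t = FrequencyTable.from_pairs([("the", 6), ("cat", 2)])
        p = tmp_path / "freq.tsv"
        t.to_tsv(p)
        t2 = FrequencyTable.from_tsv(p)
        assert t2.counts == t.counts and t2.total == t.total

    def test_generator_table_totals_match_token_count(self, small_corpus):
        assert small_corpus.freq_table.total == small_corpus.n_tokens


class TestNegLogFrequency:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(512, 1024, 1.0), (10, 10, 0.0), (2, 10, math.log2(5))],
    )
    def test_values(self, count, total, expected):
        t = FrequencyTable({"w": count, "pad": total - count} if total > count else {"w": count})
        assert neg_log_frequency("w", t) == pytest.approx(expected, abs=1e-9)

    def test_oov_returns_none(self):
        t = FrequencyTable({"w": 3})
        assert neg_log_frequency("missing", t) is None

    def test_monotone_decreasing_in_count(self):
        total = 1000
        vals = []
        for c in (1, 5, 50, 500):
            t = FrequencyTable({"w": c, "pad": total - c})
            vals.append(neg_log_frequency("w", t))
        assert vals == sorted(vals, reverse=True)


class _FixedLM:
    """Toy LM with scripted conditional probabilities and a '-' tokenizer."""

    def __init__(self, probs):
        self.probs = probs  # dict token -> prob (context-independent)

    def tokenize(self, word):
        return word.split("-")

    def conditional_prob(self, token, context):
        return self.probs.get(token, 0.0)


class TestSurprisal:
    def test_certain_continuation_is_zero_bits(self):
        lm = _FixedLM({"x": 1.0})
        assert surprisal("x", ["x"], lm) == 0.0

    def test_chain_rule_sums_subtoken_surprisals(self):
        lm = _FixedLM({"a": 0.5, "b": 0.25})
        assert surprisal("a-b", [], lm) == pytest.approx(3.0)

    def test_zero_probability_raises_with_token(self):
        lm = _FixedLM({"a": 0.5})
        with pytest.raises(ZeroProbabilityError) as exc:
            surprisal("a-zzz", [], lm)
        assert exc.value.token == "zzz"

    def test_total_invariant_to_tokenization(self):
        # the same joint probability split over one vs two sub-tokens
        lm_split = _FixedLM({"a": 0.5, "b": 0.25})
        lm_whole = _FixedLM({"a-b": 0.125})
        lm_whole.tokenize = lambda w: [w]
        assert surprisal("a-b", [], lm_split) == pytest.approx(
            surprisal("a-b", [], lm_whole)
        )

    def test_bigram_fixture_matches_hand_computation(self, toy_bigram_sentences):
        smoothing = 0.5
        lm = BigramLM.from_corpus(toy_bigram_sentences, smoothing=smoothing)
        # independent chain-rule evaluation from raw counts
        uni, big = {}, {}
        for sent in toy_bigram_sentences:
            prev = "<s>"
            for w in sent:
                uni[w] = uni.get(w, 0) + 1
                big[(prev, w)] = big.get((prev, w), 0) + 1
                prev = w
        V = len(uni)
        ctx_tot = {}
        for (p, w), c in big.items():
            ctx_tot[p] = ctx_tot.get(p, 0) + c

        def hand_surprisal(sentence, i):
            prev = "<s>" if i == 0 else sentence[i - 1]
            num = big.get((prev, sentence[i]), 0) + smoothing
            den = ctx_tot.get(prev, 0) + smoothing * V
            return -math.log2(num / den)

        for sent in toy_bigram_sentences:
            for i, w in enumerate(sent):
                assert surprisal(w, sent[:i], lm) == pytest.approx(
                    hand_surprisal(sent, i), abs=1e-12
                )

    def test_bigram_conditionals_sum_to_one(self, toy_bigram_sentences):
        lm = BigramLM.from_corpus(toy_bigram_sentences, smoothing=0.5)
        for ctx in ([], ["the"], ["cat"]):
            total = sum(lm.conditional_prob(w, ctx) for w in lm.vocab)
            assert total == pytest.approx(1.0, abs=1e-12)


class TestWordLength:
    @pytest.mark.parametrize("word,expected", [("cat", 3), ("don't", 4), ("...", 0), ("e.g.", 2)])
    def test_punctuation_excluded(self, word, expected):
        assert word_length(word) == expected

    def test_custom_punctuation_set(self):
        assert word_length("don't", punct_chars={"-"}) == 5


def _fixation_frame(annotations, skipped_indices=()):
    rows = []
    for _, r in annotations.iterrows():
        rows.append(
            {
                "participant_id": "p1",
                "trial_id": r["trial_id"],
                "word_index": r["word_index"],
                "ff": 100.0,
                "gd": 150.0,
                "tf": 200.0,
                "skipped": r["word_index"] in skipped_indices,
            }
        )
    return pd.DataFrame(rows)


class TestExclusions:
    def _annotate(self, sentences):
        words = sorted({w for s in sentences for w in s})
        table = FrequencyTable.from_pairs([(w, 1) for w in words])
        lm = BigramLM.from_corpus(sentences, smoothing=1.0)
        return annotate_sentences(sentences, table, lm)

    def test_three_word_sentence_keeps_middle_only(self):
        ann = self._annotate([["the", "cat", "sat"]])
        fix = _fixation_frame(ann)
        retained, counts = apply_exclusions(ann, fix)
        assert len(retained) == 1
        assert retained["word"].iloc[0] == "cat"
        assert counts["sentence_edge"] == 2

    def test_six_word_sentence_with_numeral_and_comma(self):
        # hand enumeration: 6 words - 2 edges - 1 numeral - 1 comma-bearing = 2
        ann = self._annotate([["the", "cat", "sat,", "on", "42", "mats"]])
        fix = _fixation_frame(ann)
        retained, counts = apply_exclusions(ann, fix)
        assert len(retained) == 2
        assert set(retained["word"]) == {"cat", "on"}
        assert counts == {
            "sentence_edge": 2,
            "punctuation": 1,
            "number": 1,
            "oov": 0,
            "skipped": 0,
        }

    def test_skipped_words_removed(self):
        ann = self._annotate([["a", "b", "c", "d", "e"]])
        fix = _fixation_frame(ann, skipped_indices={2})
        retained, counts = apply_exclusions(ann, fix)
        assert counts["skipped"] == 1
        assert set(retained["word"]) == {"b", "d"}

    def test_oov_words_removed(self):
        sentences = [["the", "cat", "zorp", "sat", "mat"]]
        table = FrequencyTable.from_pairs(
            [("the", 1), ("cat", 1), ("sat", 1), ("mat", 1)]
        )
        lm = BigramLM.from_corpus(sentences, smoothing=1.0)
        ann = annotate_sentences(sentences, table, lm)
        retained, counts = apply_exclusions(ann, _fixation_frame(ann))
        assert counts["oov"] == 1
        assert "zorp" not in set(retained["word"])

    def test_reasons_partition_removed_rows(self, small_annotations, small_measures):
        retained, counts = apply_exclusions(small_annotations, small_measures)
        assert len(retained) + sum(counts.values()) == len(small_measures)

    def test_misaligned_tables_error(self, small_annotations):
        fix = pd.DataFrame(
            {
                "participant_id": ["p1"],
                "trial_id": ["no-such-trial"],
                "word_index": [1],
                "skipped": [False],
            }
        )
        with pytest.raises(ValueError, match="misaligned"):
            apply_exclusions(small_annotations, fix)
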