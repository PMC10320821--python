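"""Word-property annotation and exclusion filtering.

Every word token is annotated with the three benchmark properties that drive
reading times: word length (punctuation excluded), negative log unigram
frequency (bits), and surprisal, the negative log conditional probability of
the word given its sentence prefix under a language model (bits). Previous-word
copies of each property are carried along to model spillover.

Exclusion filters follow standard practice for this kind of analysis: words at
sentence edges, words containing punctuation or digits, out-of-vocabulary
words, and skipped words are removed before modelling.
"""

from __future__ import annotations

import math
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyTable",
    "LanguageModel",
    "BigramLM",
    "ZeroProbabilityError",
    "word_length",
    "neg_log_frequency",
    "surprisal",
    "annotate_sentences",
    "apply_exclusions",
    "EXCLUSION_REASONS",
]

LOG2 = math.log(2.0)

EXCLUSION_REASONS = ("sentence_edge", "punctuation", "number", "oov", "skipped")


class ZeroProbabilityError(ValueError):
    """A language model assigned probability zero to a token."""

    def __init__(self, token: str, context: tuple[str, ...]):
        super().__init__(f"zero probability for token {token!r} in context {context!r}")
        self.token = token
        self.context = context


class LanguageModel(Protocol):
    """Contract for pluggable language models.

    ``tokenize`` splits a word into the model's sub-tokens (possibly just the
    word itself); ``conditional_prob`` returns p(token | preceding tokens of
    the sentence), in (0, 1]. Conditional probabilities over the vocabulary
    must sum to 1 at any context.
    """

    def tokenize(self, word: str) -> list[str]: ...

    def conditional_prob(self, token: str, context: Sequence[str]) -> float: ...


# ---------------------------------------------------------------------------
# frequency table
# ---------------------------------------------------------------------------


@dataclass
class FrequencyTable:
    """Unigram counts with case-folded lookup (configurable)."""

    counts: dict[str, int] = field(default_factory=dict)
    case_fold: bool = True

    def __post_init__(self):
        for w, c in self.counts.items():
            if c <= 0:
                raise ValueError(f"non-positive count for {w!r}: {c}")
        self.total = int(sum(self.counts.values()))

    def _key(self, word: str) -> str:
        return word.lower() if self.case_fold else word

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]], case_fold: bool = True) -> "FrequencyTable":
        counts: dict[str, int] = {}
        for word, count in pairs:
            key = word.lower() if case_fold else word
            if key in counts:
                raise ValueError(f"duplicate word in frequency table: {word!r}")
            count = int(count)
            if count <= 0:
                raise ValueError(f"non-positive count for {word!r}: {count}")
            counts[key] = count
        return cls(counts, case_fold)

    @classmethod
    def from_tsv(cls, path, case_fold: bool = True) -> "FrequencyTable":
        pairs = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"line {lineno}: expected 2 columns, got {len(fields)}")
                word, count = fields
                try:
                    count = int(count)
                except ValueError as e:
                    raise ValueError(f"line {lineno}: non-integer count {count!r}") from e
                pairs.append((word, count))
        return cls.from_pairs(pairs, case_fold)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for w in sorted(self.counts):
                fh.write(f"{w}\t{self.counts[w]}\n")

    def count(self, word: str) -> int | None:
        return self.counts.get(self._key(word))

    def prob(self, word: str) -> float | None:
        c = self.count(word)
        return None if c is None else c / self.total

    def __contains__(self, word: str) -> bool:
        return self._key(word) in self.counts

    def __len__(self) -> int:
        return len(self.counts)


def neg_log_frequency(word: str, table: FrequencyTable) -> float | None:
    """Negative log2 unigram probability in bits; None marks the word as
    out-of-vocabulary (no value is fabricated)."""
    p = table.prob(word)
    if p is None:
        return None
    return -math.log2(p)


# ---------------------------------------------------------------------------
# word length
# ---------------------------------------------------------------------------


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P")


def word_length(word: str, punct_chars: set[str] | None = None) -> int:
    """Number of characters after removing punctuation (Unicode P* categories
    by default; pass an explicit character set to override)."""
    if punct_chars is None:
        return sum(1 for ch in word if not _is_punct(ch))
    return sum(1 for ch in word if ch not in punct_chars)


def _has_punct(word: str) -> bool:
    return any(_is_punct(ch) for ch in word)


def _has_digit(word: str) -> bool:
    return any(ch.isdigit() for ch in word)


# ---------------------------------------------------------------------------
# surprisal
# ---------------------------------------------------------------------------


def surprisal(word: str, sentence_prefix: Sequence[str], lm: LanguageModel) -> float:
    """Surprisal of a word given its sentence prefix, in bits.

    The word is split into the model's sub-tokens and sub-token surprisals are
    summed, which by the chain rule equals the negative log joint probability
    of the sub-token sequence.
    """
    context: list[str] = []
    for w in sentence_prefix:
        context.extend(lm.tokenize(w))
    total = 0.0
    for tok in lm.tokenize(word):
        p = lm.conditional_prob(tok, tuple(context))
        if p <= 0.0:
            raise ZeroProbabilityError(tok, tuple(context))
        total += -math.log2(p)
        context.append(tok)
    return total


# ---------------------------------------------------------------------------
# bundled n-gram language model
# ---------------------------------------------------------------------------

BOS = "<s>"


class BigramLM:
    """Bigram language model with additive (add-lambda) smoothing.

    Whole words are the tokens (``tokenize`` is the identity split). Sentence
    boundaries condition the first word on a start symbol. Serializable to
    JSON (counts plus smoothing constant).
    """

    def __init__(self, unigram: dict[str, int], bigram: dict[str, dict[str, int]], smoothing: float = 0.0):
        if smoothing < 0:
            raise ValueError("smoothing must be >= 0")
        self.unigram = dict(unigram)
        self.bigram = {k: dict(v) for k, v in bigram.items()}
        self.smoothing = float(smoothing)
        self.vocab = sorted(self.unigram)
        self._context_totals = {c: sum(d.values()) for c, d in self.bigram.items()}

    @classmethod
    def from_corpus(cls, sentences: Iterable[Sequence[str]], smoothing: float = 0.0) -> "BigramLM":
        unigram: dict[str, int] = {}
        bigram: dict[str, dict[str, int]] = {}
        for sent in sentences:
            prev = BOS
            for w in sent:
                unigram[w] = unigram.get(w, 0) + 1
                bigram.setdefault(prev, {})
                bigram[prev][w] = bigram[prev].get(w, 0) + 1
                prev = w
        return cls(unigram, bigram, smoothing)

    def tokenize(self, word: str) -> list[str]:
        return [word]

    def conditional_prob(self, token: str, context: Sequence[str]) -> float:
        if token not in self.unigram:
            return 0.0
        prev = context[-1] if context else BOS
        row = self.bigram.get(prev, {})
        num = row.get(token, 0) + self.smoothing
        den = self._context_totals.get(prev, 0) + self.smoothing * len(self.vocab)
        if den == 0.0:
            return 0.0
        return num / den

    def to_json_dict(self) -> dict:
        return {"unigram": self.unigram, "bigram": self.bigram, "smoothing": self.smoothing}

    @classmethod
    def from_json_dict(cls, d: dict) -> "BigramLM":
        return cls(d["unigram"], d["bigram"], d["smoothing"])


# ---------------------------------------------------------------------------
# corpus annotation
# ---------------------------------------------------------------------------


def annotate_sentences(
    sentences: dict[str, Sequence[str]] | Sequence[Sequence[str]],
    freq_table: FrequencyTable,
    lm: LanguageModel,
) -> pd.DataFrame:
    """Annotate every word of every sentence with the three properties and
    their previous-word copies.

    ``sentences`` maps trial id to word list (a plain sequence gets positional
    trial ids). OOV words get NaN frequency and an ``oov`` flag; zero
    probability under the LM gets NaN surprisal and an ``lm_oov`` flag.
    Previous-word values are NaN for sentence-initial words.
    """
    if not isinstance(sentences, dict):
        sentences = {str(i): s for i, s in enumerate(sentences)}
    rows = []
    for trial_id, words in sentences.items():
        prev = {"len": np.nan, "freq": np.nan, "surp": np.nan}
        for i, w in enumerate(words):
            length = word_length(w)
            freq = neg_log_frequency(w, freq_table)
            try:
                surp = surprisal(w, words[:i], lm)
                lm_oov = False
            except ZeroProbabilityError:
                surp = np.nan
                lm_oov = True
            rows.append(
                {
                    "trial_id": str(trial_id),
                    "word_index": i,
                    "word": w,
                    "len": float(length),
                    "freq": np.nan if freq is None else freq,
                    "surp": surp,
                    "prev_len": prev["len"],
                    "prev_freq": prev["freq"],
                    "prev_surp": prev["surp"],
                    "oov": freq is None,
                    "lm_oov": lm_oov,
                    "sentence_len": len(words),
                }
            )
            prev = {"len": float(length), "freq": np.nan if freq is None else freq, "surp": surp}
    return pd.DataFrame(rows)


def apply_exclusions(
    annotations: pd.DataFrame,
    fixations: pd.DataFrame,
    oov_mode: str = "frequency",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Merge annotations onto per-participant fixation rows and apply the
    exclusion filters, in order: sentence-initial/final words, words with
    punctuation, words with digits, out-of-vocabulary words, skipped words.

    ``oov_mode`` selects what counts as out-of-vocabulary: absent from the
    frequency list ("frequency"), unknown to the language model ("lm"), or
    either ("any").

    Returns the retained rows (fixation measures joined with annotations) and
    a per-reason removal count. Reasons partition the removed rows: each row
    is counted under the first rule that removes it.
    """
    required = {"participant_id", "trial_id", "word_index"}
    if not required.issubset(fixations.columns):
        raise ValueError(f"fixation table must have columns {sorted(required)}")
    ann = annotations.copy()
    ann["trial_id"] = ann["trial_id"].astype(str)
    fix = fixations.copy()
    fix["trial_id"] = fix["trial_id"].astype(str)
    merged = fix.merge(ann, on=["trial_id", "word_index"], how="left", suffixes=("", "_ann"))
    if merged["word"].isna().any():
        missing = merged[merged["word"].isna()][["participant_id", "trial_id", "word_index"]].head()
        raise ValueError(f"fixation rows without matching annotation (misaligned tables):\n{missing}")

    if oov_mode == "frequency":
        oov = merged["oov"].to_numpy(bool)
    elif oov_mode == "lm":
        oov = merged["lm_oov"].to_numpy(bool)
    elif oov_mode == "any":
        oov = merged["oov"].to_numpy(bool) | merged["lm_oov"].to_numpy(bool)
    else:
        raise ValueError(f"unknown oov_mode {oov_mode!r}")

    words = merged["word"].astype(str)
    edge = (merged["word_index"] == 0) | (merged["word_index"] == merged["sentence_len"] - 1)
    punct = words.map(_has_punct).to_numpy(bool)
    digit = words.map(_has_digit).to_numpy(bool)
    if "skipped" in merged.columns:
        skipped = merged["skipped"].fillna(True).to_numpy(bool)
    else:
        skipped = np.zeros(len(merged), dtype=bool)

    reason = np.full(len(merged), "", dtype=object)
    for name, mask in [
        ("sentence_edge", edge.to_numpy(bool)),
        ("punctuation", punct),
        ("number", digit),
        ("oov", oov),
        ("skipped", skipped),
    ]:
        reason[(reason == "") & mask] = name
    counts = {name: int((reason == name).sum()) for name in EXCLUSION_REASONS}
    retained = merged[reason == ""].copy()
    assert len(retained) + sum(counts.values()) == len(merged)
    return retained.reset_index(drop=True), counts
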