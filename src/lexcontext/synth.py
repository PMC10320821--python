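"""Synthetic corpora, language models, participants, and reading times.

The generator emulates the statistical structure the downstream analyses
assume, so the whole pipeline is testable without access to a real eye-tracking
corpus:

* a Zipfian vocabulary read by a bigram language model whose stationary
  unigram marginal is *exactly* the target Zipf law (a Metropolis chain with
  uniform proposals), so the generative law itself is the oracle for
  frequency-distribution checks;
* word lengths correlated with frequency, as in real lexicons;
* per-participant reading-time effect curves (polynomial in each property)
  with spillover from the previous word, participant random intercepts and
  slopes, amplitude modulation by a proficiency score, and Gaussian ms-scale
  noise truncated at 1 ms;
* First Fixation and Gaze Duration generated top-down from Total Fixation by
  configurable fractions plus noise, clamped so 1 <= FF <= GD <= TF always.

All randomness flows from explicit integer seeds; identical (spec, seed) give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import FrequencyTable

__all__ = [
    "SyntheticCorpusSpec",
    "GenerativeEffectSpec",
    "ParticipantProfile",
    "ZipfBigramLM",
    "generate_corpus",
    "generate_participants",
    "generate_reading_times",
    "measures_to_events",
    "profiles_frame",
    "sample_modeling_frame",
    "generate_dataset",
    "inverted_u_amplitude",
]

L2_NATIVE_LANGUAGES = ("Arabic", "Chinese", "Japanese", "Portuguese", "Spanish")


# ---------------------------------------------------------------------------
# corpus + language model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    vocab_size: int = 1000
    zipf_exponent: float = 1.0
    n_sentences: int = 500
    sentence_length: tuple[int, int] = (5, 18)
    seed: int = 0
    length_intercept: float = 0.5
    length_slope: float = 0.6  # characters per bit of negative log-frequency
    length_jitter_sd: float = 1.2
    graph_degree: int = 20  # neighbor-graph degree of the bigram kernel
    graph_weight: float = 0.5  # share of transitions taking a graph step

    def __post_init__(self):
        if self.vocab_size < 2:
            raise ValueError("vocab_size must be >= 2")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be >= 0")
        if self.sentence_length[0] < 3:
            raise ValueError("minimum sentence length must be >= 3 so interior words survive edge exclusion")
        if self.sentence_length[0] > self.sentence_length[1]:
            raise ValueError("sentence_length range inverted")


def _encode_word(rank: int, target_len: int) -> str:
    """Unique word string of (approximately) the target length.

    The rank is written in base 25 over 'b'..'z' and left-padded with 'a';
    because 'a' never occurs in the code body, padding preserves uniqueness.
    """
    digits = []
    r = rank + 1
    while r > 0:
        digits.append("bcdefghijklmnopqrstuvwxyz"[r % 25])
        r //= 25
    body = "".join(reversed(digits))
    if len(body) >= target_len:
        return body
    return "a" * (target_len - len(body)) + body


class ZipfBigramLM:
    """True generative bigram model over the synthetic vocabulary.

    The transition kernel is a mixture: with probability ``1 - graph_weight``
    the next word is an independent draw from the Zipf unigram law; otherwise
    it is a Metropolis-Hastings step over a random symmetric neighbor graph
    (uniform proposal among the current word's neighbors, acceptance
    min(1, p_j d_i / (p_i d_j)) with d the degrees). Both component kernels
    leave the Zipf law invariant, so the stationary unigram marginal is
    *exactly* the target law, while the graph component gives conditional
    probabilities genuine word-pair structure — surprisal varies between word
    pairs of equal frequency, as in natural language. Sentence-initial words
    are drawn from the stationary law. Implements the language-model contract
    (tokenize, conditional_prob) used by the annotator.
    """

    def __init__(
        self,
        words: list[str],
        probs: np.ndarray,
        graph_degree: int = 20,
        graph_weight: float = 0.5,
        graph_seed: int = 0,
    ):
        if not (0.0 <= graph_weight < 1.0):
            raise ValueError("graph_weight must be in [0, 1)")
        self.words = list(words)
        self.p = np.asarray(probs, dtype=float)
        self.p = self.p / self.p.sum()
        self.index = {w: i for i, w in enumerate(self.words)}
        V = len(self.words)
        self._V = V
        self.graph_weight = float(graph_weight)
        # random symmetric neighbor graph (self-loops removed, union-symmetrized)
        grng = np.random.default_rng(np.random.SeedSequence([int(graph_seed), 0x6B]))
        deg = min(max(graph_degree, 1), V - 1)
        neigh: list[set[int]] = [set() for _ in range(V)]
        for i in range(V):
            cand = grng.choice(V - 1, size=deg, replace=False)
            for c in cand:
                j = int(c if c < i else c + 1)
                neigh[i].add(j)
                neigh[j].add(i)
        self._neighbors = [np.array(sorted(s), dtype=np.int64) for s in neigh]
        self._neighbor_sets = [frozenset(s) for s in neigh]
        self._deg = np.array([len(s) for s in neigh], dtype=float)
        # Metropolis stay probability per word: 1 - mean acceptance over neighbors
        stay = np.empty(V)
        for i in range(V):
            nb = self._neighbors[i]
            acc = np.minimum(1.0, self.p[nb] * self._deg[i] / (self.p[i] * self._deg[nb]))
            stay[i] = 1.0 - acc.sum() / self._deg[i]
        self._stay = stay

    def tokenize(self, word: str) -> list[str]:
        return [word]

    def _metropolis_prob(self, i: int, j: int) -> float:
        if i == j:
            return float(self._stay[i])
        if j in self._neighbor_sets[i]:
            acc = min(1.0, self.p[j] * self._deg[i] / (self.p[i] * self._deg[j]))
            return float(acc / self._deg[i])
        return 0.0

    def transition_prob(self, i: int, j: int) -> float:
        w = self.graph_weight
        return (1.0 - w) * float(self.p[j]) + w * self._metropolis_prob(i, j)

    def conditional_prob(self, token: str, context: Sequence[str]) -> float:
        j = self.index.get(token)
        if j is None:
            return 0.0
        if not context:
            return float(self.p[j])
        i = self.index.get(context[-1])
        if i is None:
            return 0.0
        return self.transition_prob(i, j)

    def sample_sentence(self, length: int, rng: np.random.Generator) -> list[int]:
        out = np.empty(length, dtype=np.int64)
        cur = int(rng.choice(self._V, p=self.p))
        out[0] = cur
        w = self.graph_weight
        for t in range(1, length):
            if rng.random() >= w:
                cur = int(rng.choice(self._V, p=self.p))
            else:
                nb = self._neighbors[cur]
                j = int(nb[rng.integers(0, nb.size)])
                acc = min(1.0, self.p[j] * self._deg[cur] / (self.p[cur] * self._deg[j]))
                if rng.random() <= acc:
                    cur = j
            out[t] = cur
        return out.tolist()

    def surprisal_bits(self, idx: Sequence[int]) -> np.ndarray:
        """Surprisal of each token of one sentence given as vocab indices."""
        idx = np.asarray(idx, dtype=np.int64)
        out = np.empty(idx.size)
        out[0] = -np.log2(self.p[idx[0]])
        for t in range(1, idx.size):
            out[t] = -np.log2(self.transition_prob(int(idx[t - 1]), int(idx[t])))
        return out


@dataclass
class Corpus:
    sentences: dict[str, list[str]]
    sentence_indices: dict[str, list[int]]
    lm: ZipfBigramLM
    freq_table: FrequencyTable
    n_tokens: int


def generate_corpus(spec: SyntheticCorpusSpec) -> Corpus:
    """Sample sentences from the Zipf bigram model.

    The returned frequency table is the exact token count of the emitted
    corpus, and the returned language model is the true generative model.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xC0]))
    V = spec.vocab_size
    ranks = np.arange(1, V + 1, dtype=float)
    probs = ranks ** (-spec.zipf_exponent)
    probs /= probs.sum()
    nlf = -np.log2(probs)
    jitter = rng.normal(0.0, spec.length_jitter_sd, V)
    target_len = np.clip(
        np.round(spec.length_intercept + spec.length_slope * nlf + jitter), 1, 15
    ).astype(int)
    words = [_encode_word(r, target_len[r]) for r in range(V)]
    lm = ZipfBigramLM(
        words,
        probs,
        graph_degree=spec.graph_degree,
        graph_weight=spec.graph_weight,
        graph_seed=spec.seed,
    )

    lengths = rng.integers(spec.sentence_length[0], spec.sentence_length[1] + 1, spec.n_sentences)
    sentences: dict[str, list[str]] = {}
    sentence_indices: dict[str, list[int]] = {}
    counts: dict[str, int] = {}
    n_tokens = 0
    for t in range(spec.n_sentences):
        idx = lm.sample_sentence(int(lengths[t]), rng)
        tid = f"t{t:05d}"
        sentence_indices[tid] = idx
        sent = [words[i] for i in idx]
        sentences[tid] = sent
        for w in sent:
            counts[w] = counts.get(w, 0) + 1
        n_tokens += len(sent)
    freq_table = FrequencyTable(counts, case_fold=True)
    return Corpus(sentences, sentence_indices, lm, freq_table, n_tokens)


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------


@dataclass
class ParticipantProfile:
    participant_id: str
    group: str  # "L1" | "L2"
    native_language: str
    mpt: int
    comprehension_accuracy: float
    rand_intercept: float = 0.0
    rand_slopes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.mpt <= 50):
            raise ValueError(f"MPT score {self.mpt} outside [0, 50]")


def generate_participants(
    n_l1: int,
    n_l2: int,
    mpt_distribution: tuple[str, tuple[float, float]] = ("normal", (30.0, 10.0)),
    random_effect_sds: dict[str, float] | None = None,
    seed: int = 0,
) -> list[ParticipantProfile]:
    """Draw participant profiles.

    L1 participants carry the maximum MPT score of 50; L2 scores are drawn
    from ``mpt_distribution`` ("uniform" over an integer range or "normal")
    truncated to [0, 50] and rounded to integers. Realized random effects are
    drawn with the given SDs (keys: "intercept", "surp", "freq", "len").
    Comprehension accuracy rises with MPT plus a little noise.
    """
    if n_l1 < 0 or n_l2 < 0:
        raise ValueError("participant counts must be >= 0")
    sds = {"intercept": 0.0, "surp": 0.0, "freq": 0.0, "len": 0.0}
    sds.update(random_effect_sds or {})
    for k, v in sds.items():
        if v < 0:
            raise ValueError(f"negative random-effect SD for {k!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA1]))
    kind, params = mpt_distribution
    profiles = []
    for i in range(n_l1 + n_l2):
        is_l1 = i < n_l1
        if is_l1:
            mpt = 50
            native = "English"
        else:
            if kind == "uniform":
                mpt = int(rng.integers(int(params[0]), int(params[1]) + 1))
            elif kind == "normal":
                mpt = int(round(float(np.clip(rng.normal(params[0], params[1]), 0, 50))))
            else:
                raise ValueError(f"unknown mpt distribution {kind!r}")
            native = L2_NATIVE_LANGUAGES[(i - n_l1) % len(L2_NATIVE_LANGUAGES)]
        acc = float(np.clip(0.55 + 0.45 * mpt / 50.0 + rng.normal(0.0, 0.05), 0.0, 1.0))
        profiles.append(
            ParticipantProfile(
                participant_id=f"{'l1' if is_l1 else 'l2'}_{i:03d}",
                group="L1" if is_l1 else "L2",
                native_language=native,
                mpt=mpt,
                comprehension_accuracy=acc,
                rand_intercept=float(rng.normal(0.0, sds["intercept"])),
                rand_slopes={
                    p: float(rng.normal(0.0, sds[p])) for p in ("surp", "freq", "len")
                },
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# reading times
# ---------------------------------------------------------------------------


def inverted_u_amplitude(mpt: float, u_scale: float = 0.5) -> float:
    """Effect-curve amplitude as a function of proficiency.

    A scaled inverted U: amplitude 1 at MPT 0 and 50, peaking at
    1 + u_scale at MPT 25. Produces the U-shaped proficiency-to-effect-size
    relation the proficiency analysis is designed to detect.
    """
    t = mpt / 50.0
    return 1.0 + u_scale * 4.0 * t * (1.0 - t)


@dataclass(frozen=True)
class GenerativeEffectSpec:
    """Generative reading-time model: per-property polynomial effects (ms,
    intercept-free, evaluated on the property value), linear spillover from
    the previous word, participant random effects, proficiency modulation of
    effect amplitude, and truncated Gaussian noise. GD and FF are fractions
    of TF plus independent noise, clamped to the inclusion ordering."""

    effects: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"surp": (5.0,), "freq": (3.0,), "len": (2.0,)}
    )
    spillover: dict[str, float] = field(
        default_factory=lambda: {"surp": 1.0, "freq": 0.5, "len": 0.5}
    )
    base_intercept: float = 150.0
    noise_sd: float = 30.0
    gd_fraction: float = 0.6
    ff_fraction: float = 0.4
    gd_noise_sd: float = 10.0
    ff_noise_sd: float = 8.0
    skip_prob: float = 0.1
    u_scale: float = 0.0  # 0 = no proficiency modulation of amplitudes

    def __post_init__(self):
        if self.noise_sd < 0 or self.gd_noise_sd < 0 or self.ff_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not (0.0 <= self.skip_prob < 1.0):
            raise ValueError("skip_prob must be in [0, 1)")

    def amplitude(self, mpt: float) -> float:
        return inverted_u_amplitude(mpt, self.u_scale) if self.u_scale else 1.0


def _poly(coefs: Sequence[float], x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    for d, c in enumerate(coefs, start=1):
        out += c * x**d
    return out


def generate_reading_times(
    corpus: Corpus,
    annotations: pd.DataFrame,
    profiles: Sequence[ParticipantProfile],
    effect_spec: GenerativeEffectSpec,
    seed: int = 0,
    regime: str = "individual",
) -> pd.DataFrame:
    """Simulate the fixation-measures table for every participant.

    Total Fixation is the generative intercept plus property effects of the
    current and previous word (per-participant amplitude and random slopes)
    plus the participant intercept and truncated Gaussian noise; GD and FF are
    fractions of TF plus noise, clamped so 1 <= FF <= GD <= TF; all three are
    rounded to integer ms. A configured proportion of words is marked skipped.
    In the "individual" regime trials are partitioned round-robin across
    participants; in the "shared" regime every participant reads every trial.
    The last fixated word of each trial is generated without a late revisit
    (TF = GD) so that every measures row is realizable as an event stream.
    """
    ann = annotations.set_index(["trial_id", "word_index"], drop=False).sort_index()
    unknown = set(ann["word"]) - set(corpus.lm.words)
    if unknown:
        raise ValueError(f"annotated words missing from corpus vocabulary: {sorted(unknown)[:5]}")
    trial_ids = list(corpus.sentences)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF1]))
    rows = []
    n_p = len(profiles)
    for pi, prof in enumerate(profiles):
        if regime == "individual":
            my_trials = trial_ids[pi::n_p] if n_p > 1 else trial_ids
        elif regime == "shared":
            my_trials = trial_ids
        else:
            raise ValueError(f"unknown regime {regime!r}")
        amp = effect_spec.amplitude(prof.mpt)
        for tid in my_trials:
            sub = ann.loc[tid]
            vals = {p: sub[p].to_numpy(float) for p in ("surp", "freq", "len")}
            prev_vals = {p: np.nan_to_num(sub[f"prev_{p}"].to_numpy(float)) for p in ("surp", "freq", "len")}
            nw = len(sub)
            tf = np.full(nw, effect_spec.base_intercept + prof.rand_intercept)
            for p in ("surp", "freq", "len"):
                coefs = effect_spec.effects.get(p, ())
                tf += amp * _poly(coefs, vals[p])
                tf += prof.rand_slopes.get(p, 0.0) * vals[p]
                tf += effect_spec.spillover.get(p, 0.0) * prev_vals[p]
            tf = tf + rng.normal(0.0, effect_spec.noise_sd, nw)
            tf = np.maximum(np.round(tf), 1.0)
            gd = np.round(effect_spec.gd_fraction * tf + rng.normal(0.0, effect_spec.gd_noise_sd, nw))
            gd = np.clip(gd, 1.0, tf)
            ff = np.round(effect_spec.ff_fraction * tf + rng.normal(0.0, effect_spec.ff_noise_sd, nw))
            ff = np.clip(ff, 1.0, gd)
            skipped = rng.random(nw) < effect_spec.skip_prob
            if skipped.all():
                skipped[rng.integers(0, nw)] = False  # keep every trial readable
            # the trial's last fixated word gets no late revisit (GD = TF):
            # a revisit appended right after its first-pass run would merge
            # with that run and make the triple unrealizable as events
            last_fixated = np.max(np.nonzero(~skipped)[0])
            gd[last_fixated] = tf[last_fixated]
            ff[last_fixated] = min(ff[last_fixated], gd[last_fixated])
            for j in range(nw):
                rows.append(
                    {
                        "participant_id": prof.participant_id,
                        "trial_id": tid,
                        "word_index": int(sub["word_index"].iloc[j]),
                        "word": sub["word"].iloc[j],
                        "ff": np.nan if skipped[j] else ff[j],
                        "gd": np.nan if skipped[j] else gd[j],
                        "tf": np.nan if skipped[j] else tf[j],
                        "skipped": bool(skipped[j]),
                    }
                )
    return pd.DataFrame(rows)


def measures_to_events(measures: pd.DataFrame) -> pd.DataFrame:
    """Emit a fixation-event stream realizing a measures table exactly.

    Per trial: a first pass visits fixated words left to right (one fixation
    of FF ms, plus one of GD - FF ms when positive), then revisits words with
    TF > GD in ascending order (one fixation of TF - GD ms). Running the
    measures computation on the events recovers FF/GD/TF exactly.
    """
    rows = []
    for (pid, tid), g in measures.groupby(["participant_id", "trial_id"], sort=False):
        g = g.sort_values("word_index")
        onset = 0.0
        fixated = g[~g["skipped"]]
        for _, r in fixated.iterrows():
            for dur in (r["ff"], r["gd"] - r["ff"]):
                if dur > 0:
                    rows.append(
                        {
                            "participant_id": pid,
                            "trial_id": tid,
                            "word_index": int(r["word_index"]),
                            "onset_ms": onset,
                            "duration_ms": float(dur),
                        }
                    )
                    onset += float(dur) + 20.0  # nominal saccade gap
        for _, r in fixated.iterrows():
            dur = r["tf"] - r["gd"]
            if dur > 0:
                rows.append(
                    {
                        "participant_id": pid,
                        "trial_id": tid,
                        "word_index": int(r["word_index"]),
                        "onset_ms": onset,
                        "duration_ms": float(dur),
                    }
                )
                onset += float(dur) + 20.0
    return pd.DataFrame(rows)


def profiles_frame(profiles: Sequence[ParticipantProfile]) -> pd.DataFrame:
    """Participant metadata as a DataFrame (one row per participant)."""
    return pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "group": p.group,
                "native_language": p.native_language,
                "mpt": p.mpt,
                "comprehension_accuracy": p.comprehension_accuracy,
            }
            for p in profiles
        ]
    )


def sample_modeling_frame(
    annotations: pd.DataFrame,
    profiles: Sequence[ParticipantProfile],
    n_rows: int,
    effect_spec: GenerativeEffectSpec,
    seed: int = 0,
    response: str = "tf",
) -> pd.DataFrame:
    """Draw a modelling-level dataset: annotated word rows resampled with
    replacement, assigned to participants, with the response generated by the
    same reading-time model as ``generate_reading_times`` (no FF/GD, no
    rounding, no skipping).

    Used for Monte-Carlo studies of the model-level tests, where regenerating
    a full corpus per replicate would be wasteful.
    """
    pool = annotations.dropna(subset=["prev_surp", "prev_freq", "prev_len"])
    if pool.empty:
        raise ValueError("annotations contain no rows with previous-word values")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD7]))
    idx = rng.integers(0, len(pool), n_rows)
    df = pool.iloc[idx][["surp", "freq", "len", "prev_surp", "prev_freq", "prev_len"]].reset_index(drop=True)
    p_idx = rng.integers(0, len(profiles), n_rows)
    df["participant_id"] = [profiles[i].participant_id for i in p_idx]
    y = np.full(n_rows, effect_spec.base_intercept)
    amps = np.array([effect_spec.amplitude(p.mpt) for p in profiles])[p_idx]
    y = y + np.array([p.rand_intercept for p in profiles])[p_idx]
    for p in ("surp", "freq", "len"):
        x = df[p].to_numpy(float)
        y += amps * _poly(effect_spec.effects.get(p, ()), x)
        slopes = np.array([pr.rand_slopes.get(p, 0.0) for pr in profiles])[p_idx]
        y += slopes * x
        y += effect_spec.spillover.get(p, 0.0) * df[f"prev_{p}"].to_numpy(float)
    y = y + rng.normal(0.0, effect_spec.noise_sd, n_rows)
    df[response] = np.maximum(y, 1.0)
    return df


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------


def generate_dataset(
    corpus_spec: SyntheticCorpusSpec,
    n_l1: int = 10,
    n_l2: int = 40,
    effect_spec: GenerativeEffectSpec | None = None,
    mpt_distribution: tuple[str, tuple[float, float]] = ("normal", (30.0, 10.0)),
    random_effect_sds: dict[str, float] | None = None,
    seed: int = 0,
    regime: str = "individual",
) -> dict:
    """Generate corpus, annotations, participants and reading times in one go.

    Returns a dict with keys corpus, annotations, profiles, measures, events.
    Annotation uses the true generative language model and the corpus's own
    frequency table, so annotated property values are the generative truth.
    """
    from .annotate import annotate_sentences

    effect_spec = effect_spec or GenerativeEffectSpec()
    corpus = generate_corpus(corpus_spec)
    ann = annotate_sentences(corpus.sentences, corpus.freq_table, corpus.lm)
    profiles = generate_participants(
        n_l1, n_l2, mpt_distribution, random_effect_sds, seed=seed + 1
    )
    measures = generate_reading_times(corpus, ann, profiles, effect_spec, seed=seed + 2, regime=regime)
    return {
        "corpus": corpus,
        "annotations": ann,
        "profiles": profiles,
        "measures": measures,
    }
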