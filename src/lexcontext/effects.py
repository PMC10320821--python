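"""Per-participant effect sizes and group comparisons.

With an additive model there is no single regression coefficient per word
property, so a participant's effect size is summarized as the *average
slowdown*: the participant's fitted partial effect for the property, evaluated
at every retained corpus word and averaged,

    slowdown_(i,p) = (1/|C|) * sum_{w in C} s_(i,p)(p(w))     [ms]

where s_(i,p) is the partial effect from a model fitted to participant i's
data alone (no random-effect terms) and C is the whole retained corpus. The
partial effect is anchored at zero (s(0) = 0), so a linear effect of slope b
contributes b * p(w) for a word with property value p(w) — e.g. a 5 ms/bit
linear surprisal effect contributes 30 ms at a 6-bit word — and the slowdown
reduces to b times the corpus mean of the property.

The lexicon-context tradeoff statistic is the per-participant difference
between the frequency and surprisal slowdowns:

    diff_i = slowdown_(i,freq) - slowdown_(i,surp)

positive values mean frequency (lexical, context-invariant) information
dominates contextual prediction for that participant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gam import (
    FitResult,
    ModelSpec,
    fit_model,
    frequency_model_spec,
    significance_stars,
    surprisal_model_spec,
)

__all__ = [
    "SlowdownEffect",
    "DiffEffect",
    "GroupComparison",
    "fit_per_participant",
    "participant_slowdown",
    "freq_surp_diff",
    "compute_all_slowdowns",
    "compute_diffs",
    "group_compare",
    "paired_compare",
]

log = logging.getLogger(__name__)

MEASURES = ("ff", "gd", "tf")
PROPERTIES = ("freq", "surp", "len")


@dataclass(frozen=True)
class SlowdownEffect:
    participant_id: str
    property: str
    measure: str
    slowdown: float
    n_out_of_range: int = 0


@dataclass(frozen=True)
class DiffEffect:
    participant_id: str
    measure: str
    diff: float


def fit_per_participant(
    data: pd.DataFrame,
    measure: str = "tf",
    which: str = "both",
    min_rows: int = 200,
    k: int = 20,
) -> dict[str, FitResult] | None:
    """Fit the benchmark models to a single participant's retained rows,
    without random-effect terms.

    ``which``: "surprisal" (the surprisal model only), "frequency" (the
    frequency/length model only) or "both". Participants with fewer than
    ``min_rows`` rows are skipped (returns None, logged).
    """
    data = data.dropna(subset=[measure])
    if len(data) < min_rows:
        pid = data["participant_id"].iloc[0] if len(data) else "<empty>"
        log.info("skipping participant %s: %d rows < minimum %d", pid, len(data), min_rows)
        return None
    out: dict[str, FitResult] = {}
    if which in ("surprisal", "both"):
        spec = surprisal_model_spec(measure, k=k, include_re=False)
        out["surprisal"] = fit_model(spec, data, keep_cov=False)
    if which in ("frequency", "both"):
        spec = frequency_model_spec(measure, k=k, include_re=False)
        out["frequency"] = fit_model(spec, data, keep_cov=False)
    return out


def participant_slowdown(
    fit: FitResult,
    corpus: pd.DataFrame,
    property: str,
) -> SlowdownEffect:
    """Average slowdown for one property: the zero-anchored partial effect
    evaluated at every retained corpus word's property value, averaged.

    Property values outside the fitted covariate range are evaluated by linear
    extension of the boundary segment; their count is recorded.
    """
    values = corpus[property].to_numpy(dtype=float)
    block = fit._find_block(property)
    if block.knots is not None:
        n_out = int(np.sum((values < block.knots[0]) | (values > block.knots[-1])))
    else:
        n_out = 0
    contribs = fit.partial_effect(property, values, anchor="zero")
    pid = corpus.attrs.get("participant_id", "")
    return SlowdownEffect(
        participant_id=pid,
        property=property,
        measure=fit.response,
        slowdown=float(np.mean(contribs)),
        n_out_of_range=n_out,
    )


def freq_surp_diff(
    fit_freq: FitResult,
    fit_surp: FitResult,
    corpus: pd.DataFrame,
) -> DiffEffect:
    """Lexicon-context tradeoff: frequency slowdown minus surprisal slowdown,
    averaged over the same corpus."""
    s_freq = participant_slowdown(fit_freq, corpus, "freq")
    s_surp = participant_slowdown(fit_surp, corpus, "surp")
    return DiffEffect(
        participant_id=corpus.attrs.get("participant_id", ""),
        measure=fit_freq.response,
        diff=s_freq.slowdown - s_surp.slowdown,
    )


def compute_all_slowdowns(
    retained: pd.DataFrame,
    measures: tuple[str, ...] = MEASURES,
    properties: tuple[str, ...] = PROPERTIES,
    min_rows: int = 200,
    k: int = 20,
    surprisal_from: str = "surprisal_model",
) -> pd.DataFrame:
    """Per-participant slowdown effects for every (property, measure).

    Frequency and length slowdowns come from the frequency/length model;
    surprisal slowdowns come from the surprisal model by default
    (``surprisal_from="frequency_model"`` reuses the frequency model's s(surp)
    term instead, halving the number of fits). The corpus C for the Eq-style
    average is the full retained table across participants.

    Returns a long DataFrame (participant_id, group, mpt, property, measure,
    slowdown, diff-ready columns).
    """
    rows = []
    meta_cols = [c for c in ("group", "mpt", "native_language", "comprehension_accuracy") if c in retained.columns]
    for measure in measures:
        corpus = retained.dropna(subset=[measure])
        for pid, sub in retained.groupby("participant_id", sort=True):
            need_surp_model = surprisal_from == "surprisal_model" and "surp" in properties
            which = "both" if need_surp_model else "frequency"
            fits = fit_per_participant(sub, measure=measure, which=which, min_rows=min_rows, k=k)
            if fits is None:
                continue
            meta = {c: sub[c].iloc[0] for c in meta_cols}
            for prop in properties:
                fit = (
                    fits["surprisal"]
                    if (prop == "surp" and "surprisal" in fits)
                    else fits["frequency"]
                )
                corpus.attrs["participant_id"] = str(pid)
                eff = participant_slowdown(fit, corpus, prop)
                rows.append(
                    {
                        "participant_id": str(pid),
                        **meta,
                        "property": prop,
                        "measure": measure,
                        "slowdown": eff.slowdown,
                        "n_out_of_range": eff.n_out_of_range,
                    }
                )
    return pd.DataFrame(rows)


def compute_diffs(slowdowns: pd.DataFrame) -> pd.DataFrame:
    """Frequency-minus-surprisal slowdown difference per participant and
    measure, computed row-by-row from the slowdown table (exact)."""
    wide = slowdowns.pivot_table(
        index=["participant_id", "measure"], columns="property", values="slowdown"
    ).reset_index()
    if not {"freq", "surp"}.issubset(wide.columns):
        raise ValueError("slowdown table must contain freq and surp rows")
    wide["diff"] = wide["freq"] - wide["surp"]
    meta_cols = [c for c in ("group", "mpt") if c in slowdowns.columns]
    if meta_cols:
        meta = slowdowns.drop_duplicates("participant_id").set_index("participant_id")[meta_cols]
        wide = wide.join(meta, on="participant_id")
    return wide[["participant_id", "measure", "diff"] + meta_cols]


@dataclass(frozen=True)
class GroupComparison:
    t: float
    p_value: float
    mean_l1: float
    ci_l1: tuple[float, float]
    mean_l2: float
    ci_l2: tuple[float, float]

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def _normal_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    m = float(np.mean(x))
    half = stats.norm.ppf(0.5 + level / 2.0) * float(np.std(x, ddof=1)) / np.sqrt(len(x))
    return (m - half, m + half)


def group_compare(l1_values, l2_values) -> GroupComparison:
    """Welch two-sample t-test on per-participant slowdowns, with group means
    and normal-approximation 95% confidence intervals."""
    l1 = np.asarray(l1_values, dtype=float)
    l2 = np.asarray(l2_values, dtype=float)
    if len(l1) < 2 or len(l2) < 2:
        raise ValueError("each group needs at least 2 participants")
    t, p = stats.ttest_ind(l1, l2, equal_var=False)
    return GroupComparison(
        t=float(t),
        p_value=float(p),
        mean_l1=float(np.mean(l1)),
        ci_l1=_normal_ci(l1),
        mean_l2=float(np.mean(l2)),
        ci_l2=_normal_ci(l2),
    )


def paired_compare(freq_values, surp_values) -> tuple[float, float]:
    """Paired t-test on per-participant (surprisal - frequency) slowdowns;
    positive t means surprisal effects exceed frequency effects."""
    freq = np.asarray(freq_values, dtype=float)
    surp = np.asarray(surp_values, dtype=float)
    if len(freq) != len(surp):
        raise ValueError("paired comparison needs equal-length columns")
    if len(freq) < 2:
        raise ValueError("need at least 2 pairs")
    if np.all(surp - freq == 0.0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(surp, freq)
    return float(t), float(p)
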