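"""Word-level fixation measures from raw fixation event streams.

Three standard measures, capturing successively later stages of processing:

* First Fixation (FF): duration of the chronologically first fixation on the
  word.
* Gaze Duration (GD): summed duration of the maximal initial run of
  consecutive fixations on the word, starting at the first fixation and ending
  when the gaze first leaves the word (first pass).
* Total Fixation (TF): summed duration of all fixations on the word in the
  trial.

The measures stand in a monotone inclusion relationship FF <= GD <= TF for
every fixated word; unfixated words are marked skipped with null measures.
Blinks and track losses are assumed to have been cleaned upstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_trial_measures", "compute_measures"]


def compute_trial_measures(
    word_indices: np.ndarray,
    durations: np.ndarray,
    onsets: np.ndarray | None = None,
) -> dict[int, tuple[float, float, float]]:
    """FF/GD/TF per fixated word for one (participant, trial) event sequence.

    Events must be in chronological order; if onsets are given they are
    validated to be non-decreasing. Durations must be positive.
    """
    word_indices = np.asarray(word_indices)
    durations = np.asarray(durations, dtype=float)
    if onsets is not None:
        onsets = np.asarray(onsets, dtype=float)
        if np.any(np.diff(onsets) < 0):
            raise ValueError("fixation onsets are not in chronological order")
    if np.any(durations <= 0):
        raise ValueError("fixation durations must be positive")

    ff: dict[int, float] = {}
    gd: dict[int, float] = {}
    tf: dict[int, float] = {}
    first_run_open: dict[int, bool] = {}
    prev_word: int | None = None
    for w, d in zip(word_indices.tolist(), durations.tolist()):
        if prev_word is not None and prev_word != w and prev_word in first_run_open:
            first_run_open[prev_word] = False  # gaze left the word: first pass over
        tf[w] = tf.get(w, 0.0) + d
        if w not in ff:
            ff[w] = d
            gd[w] = d
            first_run_open[w] = True
        elif first_run_open.get(w, False):
            gd[w] += d
        prev_word = w
    return {w: (ff[w], gd[w], tf[w]) for w in ff}


def compute_measures(
    events: pd.DataFrame,
    words: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Reduce a fixation-event table to word-level measures.

    ``events`` needs columns participant_id, trial_id, word_index, onset_ms,
    duration_ms, ordered by onset within each (participant, trial). ``words``
    optionally lists every (trial_id, word_index[, word]) so that words never
    fixated appear as skipped rows; without it only fixated words are emitted.
    """
    required = {"participant_id", "trial_id", "word_index", "onset_ms", "duration_ms"}
    if not required.issubset(events.columns):
        raise ValueError(f"events table must have columns {sorted(required)}")
    out = []
    word_lookup: dict[str, pd.DataFrame] = {}
    if words is not None:
        words = words.copy()
        words["trial_id"] = words["trial_id"].astype(str)
        word_lookup = {t: g for t, g in words.groupby("trial_id")}
    ev = events.copy()
    ev["trial_id"] = ev["trial_id"].astype(str)
    for (pid, tid), g in ev.groupby(["participant_id", "trial_id"], sort=False):
        m = compute_trial_measures(
            g["word_index"].to_numpy(),
            g["duration_ms"].to_numpy(),
            g["onset_ms"].to_numpy(),
        )
        if words is not None:
            trial_words = word_lookup.get(tid)
            if trial_words is None:
                raise ValueError(f"trial {tid!r} has fixations but no word listing")
            for _, row in trial_words.iterrows():
                wi = int(row["word_index"])
                rec = {
                    "participant_id": pid,
                    "trial_id": tid,
                    "word_index": wi,
                }
                if "word" in trial_words.columns:
                    rec["word"] = row["word"]
                if wi in m:
                    rec.update(ff=m[wi][0], gd=m[wi][1], tf=m[wi][2], skipped=False)
                else:
                    rec.update(ff=np.nan, gd=np.nan, tf=np.nan, skipped=True)
                out.append(rec)
        else:
            for wi, (ffv, gdv, tfv) in sorted(m.items()):
                out.append(
                    {
                        "participant_id": pid,
                        "trial_id": tid,
                        "word_index": int(wi),
                        "ff": ffv,
                        "gd": gdv,
                        "tf": tfv,
                        "skipped": False,
                    }
                )
    return pd.DataFrame(out)
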