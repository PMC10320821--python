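"""Tabular IO, run configuration, and seed management.

Fixation reports are UTF-8 TSV with a header in the canonical dialect; a
column map adapts other dialects (e.g. interest-area reports with different
column names). Result tables are CSV with '#'-prefixed metadata lines carrying
the config hash and seed that produced them, so every output is traceable and
round-trips losslessly.

All randomness flows from a single top-level seed through named substreams,
one per pipeline stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotate import FrequencyTable

__all__ = [
    "FixationReportRow",
    "RunConfig",
    "ConfigurationError",
    "ParseError",
    "read_fixation_report",
    "read_frequency_table",
    "write_table",
    "read_table",
    "substream_seed",
    "substream_rng",
]


class ConfigurationError(ValueError):
    pass


class ParseError(ValueError):
    def __init__(self, msg: str, line: int):
        super().__init__(f"line {line}: {msg}")
        self.line = line


@dataclass
class FixationReportRow:
    """One word token of one participant's trial: either precomputed measures
    (ff/gd/tf in ms) or a list of (onset, duration) fixation events."""

    participant_id: str
    trial_id: str
    word_index: int
    word: str
    ff: float | None = None
    gd: float | None = None
    tf: float | None = None
    events: list[tuple[float, float]] | None = None

    def __post_init__(self):
        has_measures = self.ff is not None or self.gd is not None or self.tf is not None
        if not has_measures and not self.events:
            raise ValueError("row needs either precomputed measures or fixation events")
        for v in (self.ff, self.gd, self.tf):
            if v is not None and v <= 0:
                raise ValueError(f"non-positive duration {v}")
        if self.events:
            for onset, dur in self.events:
                if dur <= 0:
                    raise ValueError(f"non-positive fixation duration {dur}")


MEASURE_COLUMNS = ("participant_id", "trial_id", "word_index", "word", "ff", "gd", "tf")
EVENT_COLUMNS = ("participant_id", "trial_id", "word_index", "word", "onset_ms", "duration_ms")


def read_fixation_report(
    path,
    column_map: dict[str, str] | None = None,
    sep: str = "\t",
) -> list[FixationReportRow]:
    """Read a fixation report (measures form or events form).

    ``column_map`` maps file column names to canonical field names, e.g.
    ``{"IA_ID": "word_index"}``. The form is detected from the mapped header:
    ff/gd/tf columns give measures rows, onset_ms/duration_ms columns give one
    event per line, which are grouped into per-word rows with event lists.
    """
    path = Path(path)
    column_map = column_map or {}
    with open(path, encoding="utf-8") as fh:
        lines = [l.rstrip("\n") for l in fh]
    lines = [(i + 1, l) for i, l in enumerate(lines) if l and not l.startswith("#")]
    if not lines:
        raise ConfigurationError(f"{path}: empty file")
    header_line_no, header = lines[0]
    names = [column_map.get(c, c) for c in header.split(sep)]
    required = {"participant_id", "trial_id", "word_index", "word"}
    missing = required - set(names)
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {sorted(missing)} (after column_map)"
        )
    is_events = "duration_ms" in names
    if not is_events and not {"ff", "gd", "tf"} & set(names):
        raise ConfigurationError(
            f"{path}: need either duration_ms/onset_ms or ff/gd/tf columns"
        )
    idx = {n: i for i, n in enumerate(names)}

    def get(fields, col, line_no, numeric=False, optional=False):
        if col not in idx:
            return None
        raw = fields[idx[col]]
        if raw in ("", "NA", "nan"):
            if optional:
                return None
            raise ParseError(f"missing value in column {col!r}", line_no)
        if numeric:
            try:
                return float(raw)
            except ValueError:
                raise ParseError(f"non-numeric value {raw!r} in column {col!r}", line_no) from None
        return raw

    rows: list[FixationReportRow] = []
    events_acc: dict[tuple, list] = {}
    words_acc: dict[tuple, str] = {}
    for line_no, line in lines[1:]:
        fields = line.split(sep)
        if len(fields) != len(names):
            raise ParseError(f"expected {len(names)} fields, got {len(fields)}", line_no)
        pid = get(fields, "participant_id", line_no)
        tid = get(fields, "trial_id", line_no)
        wi = get(fields, "word_index", line_no, numeric=True)
        if wi is None or wi != int(wi):
            raise ParseError(f"word_index must be an integer, got {wi!r}", line_no)
        word = get(fields, "word", line_no)
        key = (pid, tid, int(wi))
        if is_events:
            onset = get(fields, "onset_ms", line_no, numeric=True, optional=True)
            dur = get(fields, "duration_ms", line_no, numeric=True)
            if dur is None or dur <= 0:
                raise ParseError(f"non-positive duration {dur!r}", line_no)
            events_acc.setdefault(key, []).append((onset if onset is not None else 0.0, dur))
            words_acc[key] = word
        else:
            try:
                row = FixationReportRow(
                    participant_id=pid,
                    trial_id=tid,
                    word_index=int(wi),
                    word=word,
                    ff=get(fields, "ff", line_no, numeric=True, optional=True),
                    gd=get(fields, "gd", line_no, numeric=True, optional=True),
                    tf=get(fields, "tf", line_no, numeric=True, optional=True),
                )
            except ValueError as e:
                raise ParseError(str(e), line_no) from None
            rows.append(row)
    if is_events:
        for key, evs in events_acc.items():
            pid, tid, wi = key
            rows.append(
                FixationReportRow(
                    participant_id=pid,
                    trial_id=tid,
                    word_index=wi,
                    word=words_acc[key],
                    events=sorted(evs),
                )
            )
    else:
        seen = set()
        for r in rows:
            key = (r.participant_id, r.trial_id, r.word_index)
            if key in seen:
                raise ConfigurationError(f"duplicate (participant, trial, word_index): {key}")
            seen.add(key)
    return rows


def rows_to_frame(rows: list[FixationReportRow]) -> pd.DataFrame:
    recs = []
    for r in rows:
        recs.append(
            {
                "participant_id": r.participant_id,
                "trial_id": r.trial_id,
                "word_index": r.word_index,
                "word": r.word,
                "ff": np.nan if r.ff is None else r.ff,
                "gd": np.nan if r.gd is None else r.gd,
                "tf": np.nan if r.tf is None else r.tf,
                "skipped": r.ff is None and r.gd is None and r.tf is None and not r.events,
            }
        )
    return pd.DataFrame(recs)


def read_frequency_table(path, case_fold: bool = True) -> FrequencyTable:
    """Two-column (word, count) TSV; duplicate words or non-positive counts
    are errors. Lookup is case-folded unless disabled."""
    return FrequencyTable.from_tsv(path, case_fold=case_fold)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Paths and analysis switches for a pipeline run."""

    fixation_report: str = ""
    frequency_table: str = ""
    lm_spec: str = ""
    participants: str = ""
    measures: tuple[str, ...] = ("ff", "gd", "tf")
    bootstrap_B: int = 200
    seed: int = 0
    alpha: float = 0.05
    min_rows_per_participant: int = 200
    case_fold: bool = True

    def __post_init__(self):
        if self.bootstrap_B < 1:
            raise ConfigurationError("bootstrap_B must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must be in (0, 1)")
        self.measures = tuple(self.measures)
        for m in self.measures:
            if m not in ("ff", "gd", "tf"):
                raise ConfigurationError(f"unknown measure {m!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["measures"] = list(d["measures"])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# result tables with embedded provenance
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path, config_hash: str = "", seed: int | None = None) -> None:
    """CSV with '#'-prefixed metadata lines (config hash, seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a result table; metadata lines land in ``df.attrs``."""
    meta = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    df.attrs.update(meta)
    return df


# ---------------------------------------------------------------------------
# seed substreams
# ---------------------------------------------------------------------------


def substream_seed(seed: int, name: str) -> int:
    """Deterministic stage-specific seed derived from the top-level seed."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def substream_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(seed, name))
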