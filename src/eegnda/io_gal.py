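"""Reading/writing the grasp-and-lift Kaggle CSV dialect and result tables.

A recording is stored as a pair of CSVs: ``*_data.csv`` with an ``id``
column plus one column per channel, and ``*_events.csv`` with the same
``id`` column plus the six binary event columns in any order. The two
files must share the id sequence row-for-row. Sampling rate is not stored
in the files; it is fixed at 500 Hz with an override.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, SchemaError
from .synthdata import CLASS_NAMES, EEGRecording, EventTimeline

GAL_SAMPLING_RATE = 500.0


@dataclass
class GalFilePair:
    """Paths to a ``*_data.csv`` / ``*_events.csv`` pair."""

    data_path: Path
    events_path: Path

    def __post_init__(self) -> None:
        self.data_path = Path(self.data_path)
        self.events_path = Path(self.events_path)


def read_gal(
    pair: GalFilePair, sampling_rate: float = GAL_SAMPLING_RATE
) -> tuple[EEGRecording, EventTimeline]:
    """Read a file pair into a recording and its event timeline.

    Events are reordered into the canonical class order regardless of the
    column order on disk; the row order of the files is preserved.
    """
    data_df = pd.read_csv(pair.data_path)
    events_df = pd.read_csv(pair.events_path)

    for name, df in (("data", data_df), ("events", events_df)):
        if "id" not in df.columns:
            raise SchemaError(f"{name} file lacks an 'id' column")
    if len(data_df) != len(events_df):
        raise AlignmentError(
            f"row count mismatch: {len(data_df)} data rows vs "
            f"{len(events_df)} event rows"
        )
    if not (data_df["id"].astype(str).values == events_df["id"].astype(str).values).all():
        raise AlignmentError("id sequences of data and events files differ")

    event_cols = [c for c in events_df.columns if c != "id"]
    if set(event_cols) != set(CLASS_NAMES):
        raise SchemaError(
            f"events file must have exactly the columns {list(CLASS_NAMES)}; "
            f"got {event_cols}"
        )
    events = events_df[list(CLASS_NAMES)].to_numpy()
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event values must be 0 or 1")

    channel_cols = [c for c in data_df.columns if c != "id"]
    if not channel_cols:
        raise SchemaError("data file has no channel columns")
    data = data_df[channel_cols].to_numpy(dtype=float).T

    recording = EEGRecording(data, sampling_rate, list(channel_cols))
    timeline = EventTimeline(events.T.astype(np.int8))
    return recording, timeline


def write_gal(
    recording: EEGRecording, timeline: EventTimeline, pair: GalFilePair
) -> None:
    """Write a recording/timeline pair in the dialect :func:`read_gal` accepts."""
    if recording.n_samples != timeline.n_samples:
        raise AlignmentError(
            f"recording has {recording.n_samples} samples but timeline has "
            f"{timeline.n_samples}"
        )
    ids = [f"synth_{i}" for i in range(recording.n_samples)]

    data_df = pd.DataFrame(
        recording.data.T, columns=recording.channel_names
    )
    data_df.insert(0, "id", ids)
    data_df.to_csv(pair.data_path, index=False)

    events_df = pd.DataFrame(timeline.triggers.T, columns=list(CLASS_NAMES))
    events_df.insert(0, "id", ids)
    events_df.to_csv(pair.events_path, index=False)


#: Fixed column order of the sweep-result CSV.
RESULT_COLUMNS = (
    "n_samples",
    "offset",
    "sigma",
    "checkpoint",
    "seed",
    "class",
    "auc",
    "micro_auc",
    "macro_auc",
)


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Flatten SweepRecords into long form: one row per class plus
    micro/macro rows per record."""
    rows = []
    for rec in records:
        base = dict(
            n_samples=rec.n_samples,
            offset=rec.offset,
            sigma=rec.sigma,
            checkpoint=rec.checkpoint,
            seed=rec.seed,
            micro_auc=rec.micro_auc,
            macro_auc=rec.macro_auc,
        )
        for name, auc in zip(CLASS_NAMES, rec.per_class_auc):
            rows.append({**base, "class": name, "auc": auc})
        rows.append({**base, "class": "micro", "auc": rec.micro_auc})
        rows.append({**base, "class": "macro", "auc": rec.macro_auc})
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results(
    records: Sequence, path: Path, config: object | None = None
) -> Path:
    """Persist sweep records as a long CSV plus a JSON run manifest.

    The manifest sidecar (``<path>.manifest.json``) carries the full run
    configuration and per-record seeds so any cell can be re-run alone.
    Numeric fields survive the CSV round trip to 12+ significant digits
    (written at float64 repr precision).
    """
    if not records:
        raise ValueError("records must be non-empty")
    path = Path(path)
    frame = records_to_frame(records)
    frame.to_csv(path, index=False, float_format="%.17g")

    manifest = {
        "n_records": len(records),
        "seeds": sorted({int(rec.seed) for rec in records}),
        "config": _jsonable(config) if config is not None else None,
    }
    sidecar = path.with_name(path.name + ".manifest.json")
    sidecar.write_text(json.dumps(manifest, indent=2, default=str))
    return sidecar


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
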