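"""Event-table I/O: CSV files with onset_s, offset_s, label columns.

Timestamps are seconds from record start; intervals are half-open
[onset, offset).  These tables carry detector output (breath/apnea) and
reference annotations alike.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .apnea import ApneaEvent
from .detector import BreathEvent

__all__ = ["events_to_frame", "write_events", "read_events", "read_apneas", "read_breaths"]

COLUMNS = ["onset_s", "offset_s", "label"]


def events_to_frame(
    events: Sequence[BreathEvent | ApneaEvent], label: str
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [e.start for e in events],
            "offset_s": [e.end for e in events],
            "label": label,
        },
        columns=COLUMNS,
    )


def write_events(path: str | Path, frame: pd.DataFrame) -> None:
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    bad = frame["onset_s"] >= frame["offset_s"]
    if bad.any():
        raise ValueError("event table rows must satisfy onset_s < offset_s")
    frame[COLUMNS].to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path} missing columns {missing}")
    if (frame["onset_s"] >= frame["offset_s"]).any():
        raise ValueError(f"{path} has rows with onset_s >= offset_s")
    return frame[COLUMNS]


def _rows(path: str | Path, label: str | None) -> list[tuple[float, float]]:
    frame = read_events(path)
    if label is not None:
        frame = frame[frame["label"] == label]
    return [(float(r.onset_s), float(r.offset_s)) for r in frame.itertuples()]


def read_apneas(path: str | Path, label: str | None = "apnea") -> list[ApneaEvent]:
    """Apnea events from a table; pass label=None to take every row."""
    return [ApneaEvent(start=s, end=e) for s, e in _rows(path, label)]


def read_breaths(path: str | Path, label: str | None = "breath") -> list[BreathEvent]:
    return [BreathEvent(start=s, end=e) for s, e in _rows(path, label)]
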