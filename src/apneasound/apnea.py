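"""Apnea extraction from the breath timeline.

An apnea is the absence of any detected inspiration or expiration for
more than ``apnea_min_gap`` seconds (default 15 s, strict inequality: a
gap of exactly 15.0 s is not an apnea).  Gaps against the record
boundaries count — a record that starts or ends mid-breath-hold is
flagged; downstream scorers can exclude boundary events if they prefer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .detector import BreathEvent

__all__ = ["ApneaEvent", "detect_apneas"]


@dataclass(frozen=True, order=True)
class ApneaEvent:
    """An apneic interval [start, end) in seconds.

    ``start`` is the end of the last breath before the gap (or the record
    start); ``end`` is the start of the next breath (or the record end).
    """

    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_apneas(
    breaths: Sequence[BreathEvent],
    record_start: float,
    record_end: float,
    apnea_min_gap: float = 15.0,
) -> list[ApneaEvent]:
    """Emit one apnea per inter-breath gap strictly longer than the rule.

    ``breaths`` must be sorted, disjoint, and within the record.  The
    union of breaths, emitted apneas, and sub-threshold gaps tiles
    [record_start, record_end] without overlap.
    """
    if record_end <= record_start:
        raise ValueError(
            f"record_end ({record_end}) must exceed record_start ({record_start})"
        )
    prev_end = record_start
    for b in breaths:
        if b.start < prev_end - 1e-9 or b.end > record_end + 1e-9:
            raise ValueError("breath events must be sorted, disjoint, and inside the record")
        prev_end = b.end

    apneas = []
    gap_start = record_start
    bounds = [(b.start, b.end) for b in breaths] + [(record_end, record_end)]
    for b_start, b_end in bounds:
        if b_start - gap_start > apnea_min_gap:
            apneas.append(ApneaEvent(start=gap_start, end=b_start))
        gap_start = max(gap_start, b_end)
    return apneas
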