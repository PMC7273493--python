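"""Event-level scoring of detected apneas against reference annotations.

Detected apnea events are matched one-to-one to reference (gold standard)
events by temporal overlap: any positive overlap qualifies by default,
assignment is greedy by decreasing overlap length.  A matched reference
event is a true positive, an unmatched reference event a false negative,
and an unmatched detected event a false positive.  True negatives are
time-quantized: the total time in which neither method flags apnea is
divided by ``tn_quantum`` (default 15 s, the apnea rule length) and
floored to an integer count, which makes the 2x2 table well defined for
interval data.

From the table the six standard agreement metrics are derived:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
NPV TN/(TN+FN), accuracy (TP+TN)/N, and Cohen's kappa
(p_o - p_e)/(1 - p_e) with p_o the accuracy and p_e the chance agreement
from the row/column marginals.  A metric whose denominator is zero is
reported as NaN, never silently as 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .apnea import ApneaEvent

__all__ = ["ContingencyTable", "MetricsReport", "build_contingency", "compute_metrics"]


@dataclass(frozen=True)
class ContingencyTable:
    """Event-level 2x2 table: tp + fn equals the reference event count."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Six agreement metrics; undefined ratios are NaN."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    kappa: float


def _overlap(a: ApneaEvent, b: ApneaEvent) -> float:
    return max(0.0, min(a.end, b.end) - max(a.start, b.start))


def _union_length(events: Sequence[ApneaEvent]) -> float:
    total = 0.0
    last_end = -math.inf
    for ev in sorted(events, key=lambda e: e.start):
        start = max(ev.start, last_end)
        if ev.end > start:
            total += ev.end - start
            last_end = ev.end
        last_end = max(last_end, ev.end)
    return total


def build_contingency(
    detected: Sequence[ApneaEvent],
    reference: Sequence[ApneaEvent],
    record_duration: float,
    tn_quantum: float = 15.0,
    min_overlap: float = 0.0,
) -> ContingencyTable:
    """Match detected against reference apneas and count TP/FP/FN/TN.

    ``min_overlap`` (seconds) is the smallest overlap that may pair a
    detected with a reference event; at the default 0 any positive
    overlap qualifies.  Each detected event matches at most one reference
    event and vice versa (greedy, longest overlap first).
    """
    for ev in list(detected) + list(reference):
        if ev.start < -1e-9 or ev.end > record_duration + 1e-9:
            raise ValueError(f"event [{ev.start}, {ev.end}) outside record of {record_duration} s")

    pairs = []
    for i, d in enumerate(detected):
        for j, r in enumerate(reference):
            ov = _overlap(d, r)
            if ov > min_overlap:
                pairs.append((ov, i, j))
    # longest overlap first; index tie-breaks keep the match deterministic
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))

    matched_d: set[int] = set()
    matched_r: set[int] = set()
    for _, i, j in pairs:
        if i in matched_d or j in matched_r:
            continue
        matched_d.add(i)
        matched_r.add(j)

    tp = len(matched_r)
    fn = len(reference) - tp
    fp = len(detected) - len(matched_d)

    flagged = _union_length(list(detected) + list(reference))
    quiet = max(0.0, record_duration - flagged)
    tn = int(math.floor(quiet / tn_quantum + 1e-9))
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(table: ContingencyTable) -> MetricsReport:
    """Derive the six agreement metrics from a 2x2 table.

    Raises on an all-zero table.  Kappa is NaN when chance agreement is 1
    (only one class present on both margins).
    """
    n = table.total
    if n == 0:
        raise ValueError("all-zero contingency table has no defined metrics")
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    accuracy = (tp + tn) / n
    p_e = ((tp + fn) * (tp + fp) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = (accuracy - p_e) / (1.0 - p_e) if p_e != 1.0 else float("nan")
    return MetricsReport(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        accuracy=accuracy,
        kappa=kappa,
    )
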