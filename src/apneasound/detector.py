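"""Breath detection from tracheal sound: band-pass, log-variance, threshold.

The detection feature is the logarithm of the short-time variance
("log-var") of the band-passed sound.  Tracheal breath-sound energy is
concentrated roughly between 100 and 1000 Hz; a 150-800 Hz 5th-order
Butterworth band-pass suppresses heart sounds and low-frequency muscle
interference below and broadband hiss above.  The band-passed signal is
segmented into 20 ms windows with 75% overlap, the log of the within-window
variance is taken, and maximal runs of windows above a per-record threshold
lasting at least 0.5 s are marked as inspirations/expirations.

The threshold itself is computed by deterministic 2-class 1-D k-means on
the record's log-var values: in a usable record the values are bimodal
(silence floor vs breath bursts) and the midpoint of the two cluster
centers separates them.  A record whose two centers nearly coincide is
treated as having no detectable breaths rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .audio import AudioError, AudioSignal

__all__ = [
    "DetectorConfig",
    "LogVarSeries",
    "BreathEvent",
    "bandpass",
    "log_variance",
    "compute_threshold",
    "detect_breaths",
]


class EmptySeriesError(ValueError):
    """Signal too short to produce a single analysis window."""


@dataclass(frozen=True)
class DetectorConfig:
    """Breath-detector parameters.

    band_low / band_high : Hz
        Butterworth passband edges.
    butter_order : int
        Filter order (applied forward-backward, so effective order doubles).
    window_len : s
        Analysis window length (0.020 s -> 441 samples at 22050 Hz).
    window_overlap : fraction
        Overlap between adjacent windows; 0.75 gives a ~5 ms hop.
    min_breath_dur : s
        Minimum duration of a supra-threshold run to count as a breath.
    merge_gap : s
        Supra-threshold runs separated by less than this are merged before
        the duration test; absorbs single-window dropouts at the 5 ms hop
        while staying well below any physiologic pause.
    variance_floor
        Lower clamp on the window variance before the log (unit-full-scale
        input assumed); keeps digital silence finite.
    min_center_separation : log-var units
        k-means centers closer than this mean the record is unimodal; the
        threshold then falls back to max + fallback_margin (nothing
        detected — conservative).
    """

    band_low: float = 150.0
    band_high: float = 800.0
    butter_order: int = 5
    window_len: float = 0.020
    window_overlap: float = 0.75
    min_breath_dur: float = 0.5
    merge_gap: float = 0.25
    variance_floor: float = 1e-12
    min_center_separation: float = 1.0
    fallback_margin: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("require 0 < band_low < band_high")
        if not 0 <= self.window_overlap < 1:
            raise ValueError("window_overlap must be in [0, 1)")
        if not self.min_breath_dur > 0:
            raise ValueError("min_breath_dur must be > 0")
        if not self.variance_floor > 0:
            raise ValueError("variance_floor must be > 0")

    def window_samples(self, rate: float) -> int:
        return int(round(self.window_len * rate))

    def hop_samples(self, rate: float) -> int:
        return max(1, int(round(self.window_samples(rate) * (1.0 - self.window_overlap))))


@dataclass(frozen=True)
class LogVarSeries:
    """Log of the windowed variance, with window-center timestamps (s)."""

    times: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return self.times.shape[0]


@dataclass(frozen=True, order=True)
class BreathEvent:
    """A detected inspiration or expiration, [start, end) in seconds."""

    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def bandpass(signal: AudioSignal, config: DetectorConfig = DetectorConfig()) -> AudioSignal:
    """Zero-phase Butterworth band-pass.

    Applied forward-backward (``sosfiltfilt``) so event timestamps stay
    aligned with reference annotations.  Requires rate > 2 * band_high.
    """
    if signal.rate <= 2.0 * config.band_high:
        raise AudioError(
            f"rate {signal.rate} Hz too low for passband up to {config.band_high} Hz"
        )
    sos = sps.butter(
        config.butter_order,
        [config.band_low, config.band_high],
        btype="bandpass",
        fs=signal.rate,
        output="sos",
    )
    return signal.with_samples(sps.sosfiltfilt(sos, signal.samples))


def log_variance(signal: AudioSignal, config: DetectorConfig = DetectorConfig()) -> LogVarSeries:
    """Windowed log-variance of the signal.

    Window = round(window_len * rate) samples, hop = round(window *
    (1 - overlap)); a trailing partial window is dropped.  Variance is the
    population (1/N) variance, clamped at ``variance_floor`` before the log.
    """
    win = config.window_samples(signal.rate)
    hop = config.hop_samples(signal.rate)
    if len(signal) < win:
        raise EmptySeriesError(
            f"signal of {len(signal)} samples shorter than one {win}-sample window"
        )
    windows = sliding_window_view(signal.samples, win)[::hop]
    var = windows.var(axis=1)
    values = np.log(np.maximum(var, config.variance_floor))
    centers = (np.arange(windows.shape[0]) * hop + (win - 1) / 2.0) / signal.rate
    return LogVarSeries(times=centers, values=values)


def compute_threshold(series: LogVarSeries, config: DetectorConfig = DetectorConfig()) -> float:
    """Per-record log-var threshold via deterministic 2-class 1-D k-means.

    Centers are initialized at the 10th and 90th percentiles and iterated
    to convergence; the threshold is the midpoint of the two centers.  If
    the centers end up closer than ``min_center_separation`` the record is
    effectively unimodal and the returned threshold exceeds every value,
    so nothing is detected.
    """
    if len(series) == 0:
        raise EmptySeriesError("cannot compute a threshold from an empty series")
    v = series.values
    vmax = float(v.max())
    lo, hi = np.percentile(v, [10.0, 90.0])
    if hi - lo == 0.0:
        return vmax + config.fallback_margin
    c_lo, c_hi = float(lo), float(hi)
    for _ in range(200):
        mid = 0.5 * (c_lo + c_hi)
        low_mask = v <= mid
        if not low_mask.any() or low_mask.all():
            break
        new_lo = float(v[low_mask].mean())
        new_hi = float(v[~low_mask].mean())
        if new_lo == c_lo and new_hi == c_hi:
            break
        c_lo, c_hi = new_lo, new_hi
    if c_hi - c_lo < config.min_center_separation:
        return vmax + config.fallback_margin
    return 0.5 * (c_lo + c_hi)


def detect_breaths(
    series: LogVarSeries,
    threshold: float,
    config: DetectorConfig = DetectorConfig(),
) -> list[BreathEvent]:
    """Mark breaths: supra-threshold runs lasting >= min_breath_dur.

    Runs of consecutive windows with value > threshold are found, runs
    separated by less than ``merge_gap`` seconds are merged, and merged
    runs shorter than ``min_breath_dur`` are discarded.  Event boundaries
    are the first/last window-center times of the run.
    """
    if len(series) == 0:
        raise EmptySeriesError("cannot detect breaths on an empty series")
    mask = series.values > threshold
    if not mask.any():
        return []
    edges = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # exclusive
    if mask[0]:
        starts = np.insert(starts, 0, 0)
    if mask[-1]:
        ends = np.append(ends, len(mask))

    t = series.times
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        prev = merged[-1]
        if t[s] - t[prev[1] - 1] < config.merge_gap:
            prev[1] = int(e)
        else:
            merged.append([int(s), int(e)])

    events = []
    for s, e in merged:
        start, end = float(t[s]), float(t[e - 1])
        if end - start >= config.min_breath_dur - 1e-9:
            events.append(BreathEvent(start=start, end=end))
    return events
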