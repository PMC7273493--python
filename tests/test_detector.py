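"""Breath detector: band-pass response, log-var windowing, thresholding."""

import numpy as np
import pytest

from apneasound.audio import AudioError, AudioSignal
from apneasound.detector import (
    BreathEvent,
    DetectorConfig,
    EmptySeriesError,
    LogVarSeries,
    bandpass,
    compute_threshold,
    detect_breaths,
    log_variance,
)

from conftest import RATE

CFG = DetectorConfig()
HOP_S = 110 / RATE  # default 441-sample window, 110-sample hop at 22050 Hz


def _sine(freq, dur=2.0):
    t = np.arange(int(dur * RATE)) / RATE
    return AudioSignal(np.sin(2 * np.pi * freq * t), RATE)


def _rms(x):
    return np.sqrt(np.mean(x**2))


class TestBandpass:
    def test_stopband_tone_attenuated(self):
        """A 100 Hz tone sits below the 150 Hz edge: at least 20 dB down."""
        out = bandpass(_sine(100.0), CFG)
        mid = slice(int(0.5 * RATE), int(1.5 * RATE))  # skip edge transients
        drop_db = 20 * np.log10(_rms(out.samples[mid]) / _rms(_sine(100.0).samples[mid]))
        assert drop_db <= -20.0

    def test_passband_tone_preserved(self):
        """A 400 Hz mid-band tone passes within 1 dB."""
        out = bandpass(_sine(400.0), CFG)
        mid = slice(int(0.5 * RATE), int(1.5 * RATE))
        drop_db = 20 * np.log10(_rms(out.samples[mid]) / _rms(_sine(400.0).samples[mid]))
        assert abs(drop_db) <= 1.0

    def test_zero_in_zero_out(self):
        out = bandpass(AudioSignal(np.zeros(4096), RATE), CFG)
        np.testing.assert_array_equal(out.samples, np.zeros(4096))

    def test_length_preserved(self, white_signal):
        assert len(bandpass(white_signal, CFG)) == len(white_signal)

    def test_rate_too_low_rejected(self):
        with pytest.raises(AudioError):
            bandpass(AudioSignal(np.zeros(4096), 1000.0), CFG)


class TestLogVariance:
    def test_window_count_one_second(self, white_signal):
        """1 s at 22050 Hz, 441-sample windows, 110-sample hop -> 197 windows."""
        series = log_variance(white_signal, CFG)
        assert len(series) == 197

    def test_hop_is_five_ms(self, white_signal):
        series = log_variance(white_signal, CFG)
        np.testing.assert_allclose(np.diff(series.times), 110 / RATE)

    def test_constant_signal_hits_variance_floor(self):
        series = log_variance(AudioSignal(np.full(2205, 0.3), RATE), CFG)
        np.testing.assert_allclose(series.values, np.log(CFG.variance_floor))

    def test_unit_variance_noise_has_zero_mean_logvar(self, white_signal):
        """Window variance of N(0,1) noise averages 1, so log-var ~ 0."""
        series = log_variance(white_signal, CFG)
        assert abs(series.values.mean()) < 0.05

    def test_too_short_signal_rejected(self):
        with pytest.raises(EmptySeriesError):
            log_variance(AudioSignal(np.zeros(100), RATE), CFG)


def _series(values, hop=HOP_S):
    values = np.asarray(values, dtype=float)
    return LogVarSeries(times=np.arange(len(values)) * hop, values=values)


class TestThreshold:
    def test_bimodal_sample_split_between_modes(self):
        """Half N(-8, 0.2), half N(-2, 0.2): threshold lands between them."""
        rng = np.random.default_rng(1)
        values = np.concatenate(
            [rng.normal(-8, 0.2, 500), rng.normal(-2, 0.2, 500)]
        )
        thr = compute_threshold(_series(values), CFG)
        assert -7.0 < thr < -3.0

    def test_constant_series_detects_nothing(self):
        series = _series(np.full(100, -5.0))
        thr = compute_threshold(series, CFG)
        assert not (series.values > thr).any()

    def test_near_unimodal_series_detects_nothing(self):
        rng = np.random.default_rng(2)
        series = _series(rng.normal(-5.0, 0.1, 400))
        thr = compute_threshold(series, CFG)
        assert not (series.values > thr).any()

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(-9, 0.5, 300), rng.normal(-3, 0.5, 300)])
        assert compute_threshold(_series(values), CFG) == compute_threshold(
            _series(values), CFG
        )

    def test_separates_breath_from_silence_on_clean_record(self, clean_minute_record):
        """On a noise-free synthetic record the threshold reproduces the
        simulator's window labels (breath vs silence) almost perfectly."""
        filtered = bandpass(clean_minute_record.clean, CFG)
        series = log_variance(filtered, CFG)
        thr = compute_threshold(series, CFG)
        predicted = series.values > thr
        truth = np.zeros(len(series), dtype=bool)
        for b in clean_minute_record.true_breaths:
            truth |= (series.times >= b.start) & (series.times <= b.end)
        agreement = np.mean(predicted == truth)
        assert agreement >= 0.95


class TestDetectBreaths:
    def test_short_burst_rejected(self):
        """A run above threshold lasting only ~0.3 s is not a breath."""
        values = np.full(400, -20.0)
        values[100 : 100 + 60] = -3.0  # 60 windows * ~5 ms = 0.3 s
        events = detect_breaths(_series(values), -10.0, CFG)
        assert events == []

    def test_ten_bursts_give_ten_events(self):
        """Ten 1 s supra-threshold bursts spaced 4 s apart -> 10 events."""
        n_per_s = int(round(1 / HOP_S))
        values = np.full(41 * n_per_s, -20.0)
        for k in range(10):
            start = int(round((0.5 + 4.0 * k) / HOP_S))
            values[start : start + n_per_s + 1] = -3.0
        events = detect_breaths(_series(values), -10.0, CFG)
        assert len(events) == 10
        for ev in events:
            assert ev.duration >= CFG.min_breath_dur - 1e-9

    def test_all_below_threshold_gives_empty_list(self):
        assert detect_breaths(_series(np.full(300, -20.0)), -10.0, CFG) == []

    def test_events_sorted_disjoint_and_long_enough(self):
        rng = np.random.default_rng(7)
        values = np.where(rng.random(5000) < 0.5, -3.0, -20.0)
        events = detect_breaths(_series(values), -10.0, CFG)
        for prev, nxt in zip(events, events[1:]):
            assert prev.end < nxt.start
        for ev in events:
            assert ev.duration >= CFG.min_breath_dur - 1e-9

    def test_gap_merging_bridges_dropouts(self):
        """A single-window dropout inside a burst does not split the event."""
        n_per_s = int(round(1 / HOP_S))
        values = np.full(3 * n_per_s, -20.0)
        values[n_per_s : 2 * n_per_s] = -3.0
        values[n_per_s + 50] = -20.0  # dropout
        events = detect_breaths(_series(values), -10.0, CFG)
        assert len(events) == 1

    @pytest.mark.parametrize("low, high", [(-15.0, -8.0), (-12.0, -5.0)])
    def test_raising_threshold_never_increases_breath_time(self, low, high):
        rng = np.random.default_rng(13)
        values = rng.normal(-10.0, 4.0, 4000)
        total = {
            thr: sum(ev.duration for ev in detect_breaths(_series(values), thr, CFG))
            for thr in (low, high)
        }
        assert total[high] <= total[low] + 1e-9
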