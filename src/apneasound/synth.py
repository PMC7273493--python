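"""Synthetic two-microphone tracheal recordings with ground truth.

The generator emulates the breath-hold protocol used to validate acoustic
apnea detection: after a lead-in of normal resting breathing, the subject
holds their breath for ~20 s once every 40 s, ten times, for a total
record of ~15 minutes, in either a quiet room or one where a speaker
plays television dialogue.

The model is deliberately simple and places all breath-sound energy in
the detector's 150-800 Hz passband:

* clean tracheal sound — white noise band-passed to 150-800 Hz,
  amplitude-modulated by Tukey (tapered-cosine) burst envelopes, one
  inspiration and one expiration burst per breathing cycle, with the
  envelope held at zero during scheduled breath-holds;
* reference channel — the ambient noise alone: silence, white noise, or
  a speech-like process (white noise shaped by an all-pole spectrum with
  formant-like resonances, then 2-8 Hz syllabic amplitude modulation);
* primary channel — clean sound plus the reference noise convolved with
  a random unit-norm FIR coupling path (default 64 taps, matching the
  canceller's modeling capacity) and scaled either by an explicit gain
  or to hit a requested input SNR.

Every draw goes through one seeded generator, so a given protocol is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal as sps

from .apnea import ApneaEvent
from .audio import AudioSignal
from .detector import BreathEvent

__all__ = ["SynthProtocol", "SynthRecord", "generate"]


@dataclass(frozen=True)
class SynthProtocol:
    """Parameters of one simulated recording session.

    Defaults mirror the validation protocol: 900 s record, 120 s resting
    lead-in, then ten 40 s cycles each containing a 20 s central
    breath-hold, breathing at one cycle per 4 s otherwise.
    """

    total_duration: float = 900.0
    rate: float = 22050.0
    lead_in: float = 120.0
    breath_period: float = 4.0
    burst_duration: float = 1.0
    apnea_duration: float = 20.0
    apnea_cycle: float = 40.0
    apnea_count: int = 10
    noise_kind: Literal["none", "speech_like", "white"] = "none"
    noise_gain: float = 1.0
    target_snr_db: float | None = None
    coupling_taps: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("total_duration", "breath_period", "burst_duration",
                     "apnea_duration", "apnea_cycle"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.apnea_count < 0 or self.lead_in < 0:
            raise ValueError("apnea_count and lead_in must be non-negative")
        if self.lead_in + self.apnea_count * self.apnea_cycle > self.total_duration + 1e-9:
            raise ValueError("apnea schedule does not fit in total_duration")
        if self.apnea_duration >= self.apnea_cycle:
            raise ValueError("apnea_duration must leave breathing room inside apnea_cycle")
        if 2 * self.burst_duration >= self.breath_period:
            raise ValueError("two bursts per breath_period must fit with gaps")
        if self.noise_kind not in ("none", "speech_like", "white"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")

    def apnea_schedule(self) -> list[ApneaEvent]:
        """Scheduled breath-hold intervals, centred in each apnea cycle."""
        pad = (self.apnea_cycle - self.apnea_duration) / 2.0
        return [
            ApneaEvent(
                start=self.lead_in + i * self.apnea_cycle + pad,
                end=self.lead_in + i * self.apnea_cycle + pad + self.apnea_duration,
            )
            for i in range(self.apnea_count)
        ]

    def breath_schedule(self) -> list[BreathEvent]:
        """Burst intervals on the breathing grid, skipping breath-holds."""
        apneas = self.apnea_schedule()
        gap = (self.breath_period - 2.0 * self.burst_duration) / 2.0
        insp_off = gap / 2.0
        exp_off = insp_off + self.burst_duration + gap
        bursts = []
        t = 0.0
        while t + self.breath_period <= self.total_duration + 1e-9:
            for off in (insp_off, exp_off):
                start, end = t + off, t + off + self.burst_duration
                if end > self.total_duration:
                    continue
                if any(start < a.end and end > a.start for a in apneas):
                    continue
                bursts.append(BreathEvent(start=start, end=end))
            t += self.breath_period
        return bursts


@dataclass(frozen=True)
class SynthRecord:
    """One generated recording with its ground-truth annotations."""

    primary: AudioSignal
    reference: AudioSignal
    clean: AudioSignal
    true_breaths: list[BreathEvent]
    true_apneas: list[ApneaEvent]


def _breath_band_sos(rate: float):
    return sps.butter(5, [150.0, 800.0], btype="bandpass", fs=rate, output="sos")


def _clean_tracheal(protocol: SynthProtocol, rng: np.random.Generator) -> np.ndarray:
    n = int(round(protocol.total_duration * protocol.rate))
    carrier = sps.sosfiltfilt(_breath_band_sos(protocol.rate), rng.standard_normal(n))
    carrier /= max(carrier.std(), 1e-30)
    envelope = np.zeros(n)
    for b in protocol.breath_schedule():
        i0 = int(round(b.start * protocol.rate))
        i1 = min(int(round(b.end * protocol.rate)), n)
        if i1 > i0:
            envelope[i0:i1] = sps.windows.tukey(i1 - i0, alpha=0.5)
    return 0.2 * carrier * envelope


def _speech_like(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Formant-shaped noise with syllabic (2-8 Hz) amplitude modulation."""
    excitation = rng.standard_normal(n)
    a = np.array([1.0])
    for freq, radius in ((500.0, 0.97), (1500.0, 0.95), (2500.0, 0.92)):
        theta = 2.0 * np.pi * freq / rate
        pole = np.array([1.0, -2.0 * radius * np.cos(theta), radius * radius])
        a = np.convolve(a, pole)
    shaped = sps.lfilter([1.0], a, excitation)
    sos = sps.butter(2, [2.0, 8.0], btype="bandpass", fs=rate, output="sos")
    syllabic = sps.sosfiltfilt(sos, rng.standard_normal(n))
    envelope = 0.1 + np.abs(syllabic) / max(syllabic.std(), 1e-30)
    out = shaped * envelope
    return out / max(out.std(), 1e-30)


def generate(protocol: SynthProtocol) -> SynthRecord:
    """Generate one two-channel record plus ground truth, deterministically.

    With ``target_snr_db`` set, the coupled-noise gain is solved from the
    measured variance ratio so that the primary channel's input SNR
    (clean vs coupled noise) equals the target exactly; otherwise
    ``noise_gain`` scales the coupled noise directly.
    """
    rng = np.random.default_rng(protocol.seed)
    n = int(round(protocol.total_duration * protocol.rate))
    clean = _clean_tracheal(protocol, rng)

    if protocol.noise_kind == "none":
        reference = np.zeros(n)
        primary = clean.copy()
    else:
        if protocol.noise_kind == "white":
            reference = rng.standard_normal(n)
        else:
            reference = _speech_like(n, protocol.rate, rng)
        h = rng.standard_normal(protocol.coupling_taps)
        h /= np.linalg.norm(h)
        coupled = sps.lfilter(h, [1.0], reference)
        if protocol.target_snr_db is not None:
            gain = np.sqrt(
                np.var(clean) / np.var(coupled) * 10.0 ** (-protocol.target_snr_db / 10.0)
            )
        else:
            gain = protocol.noise_gain
        primary = clean + gain * coupled

    rate = protocol.rate
    return SynthRecord(
        primary=AudioSignal(primary, rate),
        reference=AudioSignal(reference, rate),
        clean=AudioSignal(clean, rate),
        true_breaths=protocol.breath_schedule(),
        true_apneas=protocol.apnea_schedule(),
    )


def breath_segment(
    duration: float = 20.0, rate: float = 22050.0, seed: int = 0
) -> AudioSignal:
    """A short apnea-free clean breathing segment, for mixture experiments."""
    protocol = SynthProtocol(
        total_duration=duration, rate=rate, lead_in=0.0, apnea_count=0, seed=seed
    )
    return generate(protocol).clean


def noise_segment(
    duration: float = 20.0,
    rate: float = 22050.0,
    seed: int = 0,
    kind: Literal["speech_like", "white"] = "speech_like",
) -> AudioSignal:
    """A matching ambient-noise segment (unit variance)."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    if kind == "white":
        samples = rng.standard_normal(n)
    else:
        samples = _speech_like(n, rate, rng)
    return AudioSignal(samples, rate)
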