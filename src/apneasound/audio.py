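"""Uniformly sampled audio container and WAV file I/O.

:class:`AudioSignal` is the carrier passed between every processing stage:
a 1-D float64 sample array plus its sampling rate.  Tracheal-sound
recordings in this package are conventionally mono, 22050 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile


class AudioError(ValueError):
    """Invalid audio input (non-finite samples, rate/length mismatch, ...)."""


@dataclass(frozen=True)
class AudioSignal:
    """A mono waveform with its sampling rate.

    Parameters
    ----------
    samples
        1-D array of amplitudes in arbitrary linear units.  Coerced to
        float64; must be finite everywhere.
    rate
        Sampling rate in samples/second, strictly positive.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1:
            raise AudioError(f"samples must be 1-D, got shape {arr.shape}")
        if not np.isfinite(arr).all():
            raise AudioError("samples contain NaN or infinity")
        if not self.rate > 0:
            raise AudioError(f"rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "rate", float(self.rate))

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self) / self.rate

    def with_samples(self, samples: np.ndarray) -> "AudioSignal":
        """A new signal at the same rate with different samples."""
        return AudioSignal(samples, self.rate)


_INT_SCALES = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


def read_wav(path: str | Path, channel: int | None = None) -> AudioSignal:
    """Read a WAV file into an :class:`AudioSignal`.

    Integer PCM is normalized to [-1, 1] full scale; float PCM is passed
    through.  Multi-channel files require an explicit ``channel`` index —
    silently picking one invites channel-swap bugs in a two-microphone
    setup.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim == 2:
        if channel is None:
            raise AudioError(
                f"{path} has {data.shape[1]} channels; pass channel= to select one"
            )
        if not 0 <= channel < data.shape[1]:
            raise AudioError(f"channel {channel} out of range for {path}")
        data = data[:, channel]
    elif channel not in (None, 0):
        raise AudioError(f"{path} is mono; channel {channel} does not exist")

    if data.dtype in _INT_SCALES:
        samples = data.astype(np.float64) / _INT_SCALES[data.dtype]
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype.kind == "f":
        samples = data.astype(np.float64)
    else:
        raise AudioError(f"unsupported WAV encoding {data.dtype} in {path}")
    return AudioSignal(samples, float(rate))


def write_wav(path: str | Path, signal: AudioSignal, subtype: str = "float32") -> None:
    """Write a mono WAV file.

    ``subtype`` is ``"float32"`` (default, lossless to ~1e-7) or ``"int16"``
    (values clipped to [-1, 1] and quantized to 16 bits).
    """
    if subtype == "float32":
        data = signal.samples.astype(np.float32)
    elif subtype == "int16":
        clipped = np.clip(signal.samples, -1.0, 32767.0 / 32768.0)
        data = np.round(clipped * 32768.0).astype(np.int16)
    else:
        raise AudioError(f"unsupported write subtype {subtype!r}")
    wavfile.write(str(path), int(round(signal.rate)), data)
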