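"""NLMS adaptive noise cancellation for two-microphone recordings.

The primary microphone (under the plastic bell at the suprasternal notch)
captures tracheal sound d(n) contaminated by ambient noise; the reference
microphone outside the bell captures the ambient noise x(n) alone.  A
normalized least-mean-squares (NLMS) transversal filter estimates the
noise component that leaks into the primary channel and subtracts it:

    y(n)   = w(n)^T x_vec(n)                       (noise estimate)
    e(n)   = d(n) - y(n)                           (denoised output)
    w(n+1) = w(n) + mu / (x_vec(n)^T x_vec(n) + psi) * e(n) * x_vec(n)

where x_vec(n) holds the most recent ``filter_order`` reference samples.
The step size is normalized by the instantaneous tap energy, so the
filter tracks nonstationary noise (speech, alarms) without step-size
retuning; ``psi`` keeps the update finite when the reference is silent.

The whole recursion runs in float64; e(n) differences drive the weight
update, so precision loss there would bias convergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .audio import AudioError, AudioSignal

__all__ = ["NLMSConfig", "NLMSState", "nlms_cancel", "DEFAULT_NLMS"]


@dataclass(frozen=True)
class NLMSConfig:
    """NLMS parameters.

    Defaults (mu=0.08, psi=0.02, 64 taps) are the preset tuned for
    tracheal recordings with an ambient-noise reference channel at
    22050 Hz.
    """

    step_size_mu: float = 0.08
    regularizer_psi: float = 0.02
    filter_order: int = 64

    def __post_init__(self) -> None:
        if not self.step_size_mu > 0:
            raise ValueError(f"step_size_mu must be > 0, got {self.step_size_mu}")
        if not self.regularizer_psi > 0:
            # psi > 0 guarantees the normalization denominator is never zero
            raise ValueError(f"regularizer_psi must be > 0, got {self.regularizer_psi}")
        if int(self.filter_order) != self.filter_order or self.filter_order < 1:
            raise ValueError(f"filter_order must be a positive integer, got {self.filter_order}")


DEFAULT_NLMS = NLMSConfig()


@dataclass(frozen=True)
class NLMSState:
    """Filter state after a run: tap weights w(n) and the final tap buffer.

    ``weights[k]`` multiplies the reference sample k steps in the past;
    ``tap_buffer`` is ordered newest-first to match.
    """

    weights: np.ndarray
    tap_buffer: np.ndarray


@njit(cache=True)
def _nlms_kernel(d, x, mu, psi, order):  # pragma: no cover - exercised via nlms_cancel
    n = d.shape[0]
    w = np.zeros(order, dtype=np.float64)
    buf = np.zeros(order, dtype=np.float64)  # newest-first
    e = np.empty(n, dtype=np.float64)
    for i in range(n):
        for k in range(order - 1, 0, -1):
            buf[k] = buf[k - 1]
        buf[0] = x[i]
        y = 0.0
        energy = 0.0
        for k in range(order):
            y += w[k] * buf[k]
            energy += buf[k] * buf[k]
        ei = d[i] - y
        e[i] = ei
        g = mu * ei / (energy + psi)
        for k in range(order):
            w[k] += g * buf[k]
    return e, w, buf


def nlms_cancel(
    primary: AudioSignal,
    reference: AudioSignal,
    config: NLMSConfig = DEFAULT_NLMS,
    return_state: bool = False,
) -> AudioSignal | tuple[AudioSignal, NLMSState]:
    """Cancel the reference-correlated noise in the primary channel.

    Returns the error signal e(n) = d(n) - y(n) — the denoised tracheal
    sound — with the same length and rate as the inputs.  Weights start at
    zero and the tap buffer is zero-padded before sample ``filter_order``,
    so a silent reference leaves the primary untouched and output stays
    aligned with the input (no warm-up trimming).

    Raises :class:`AudioError` on length or rate mismatch.
    """
    if len(primary) != len(reference):
        raise AudioError(
            f"primary ({len(primary)}) and reference ({len(reference)}) lengths differ"
        )
    if primary.rate != reference.rate:
        raise AudioError(
            f"primary rate {primary.rate} != reference rate {reference.rate}"
        )
    e, w, buf = _nlms_kernel(
        primary.samples,
        reference.samples,
        float(config.step_size_mu),
        float(config.regularizer_psi),
        int(config.filter_order),
    )
    out = AudioSignal(e, primary.rate)
    if return_state:
        return out, NLMSState(weights=w, tap_buffer=buf)
    return out
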