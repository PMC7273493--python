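import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from apneasound.audio import AudioSignal
from apneasound.synth import SynthProtocol, generate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

RATE = 22050.0


def nlms_oracle(d, x, mu=0.08, psi=0.02, order=64):
    """Straight-loop per-sample NLMS recursion, independent of the package.

    Tap buffer newest-first, zero weights and zero buffer at start:
    y(n) = w.buf, e(n) = d(n) - y(n), w += mu/(buf.buf + psi) * e(n) * buf.
    """
    d = np.asarray(d, dtype=float)
    x = np.asarray(x, dtype=float)
    w = np.zeros(order)
    buf = np.zeros(order)
    e = np.zeros(len(d))
    for n in range(len(d)):
        buf = np.concatenate(([x[n]], buf[:-1]))
        e[n] = d[n] - w @ buf
        w = w + mu * e[n] / (buf @ buf + psi) * buf
    return e


@pytest.fixture(scope="session")
def clean_minute_record():
    """60 s clean record, one scheduled 20 s breath-hold, no noise."""
    protocol = SynthProtocol(
        total_duration=60.0, lead_in=8.0, apnea_count=1, apnea_cycle=30.0, seed=11
    )
    return generate(protocol)


@pytest.fixture
def white_signal():
    rng = np.random.default_rng(42)
    return AudioSignal(rng.standard_normal(int(RATE)), RATE)
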