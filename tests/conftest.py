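import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tone(freq, rate, duration, phase=0.0):
    t = np.arange(int(round(duration * rate))) / rate
    return np.sin(2 * np.pi * freq * t + phase)


def ar1(n, rho, rng, sd=1.0):
    w = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = w[0] / np.sqrt(1 - rho ** 2)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + w[t]
    return sd * out * np.sqrt(1 - rho ** 2)
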