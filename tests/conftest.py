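import numpy as np
import pytest

import sasod


@pytest.fixture(scope="session")
def sas_recording():
    """One seeded SAS-profile recording shared across tests."""
    return sasod.gen_breath_recording("SAS", 120.0, 8000.0, seed=1)


@pytest.fixture(scope="session")
def normal_recording():
    return sasod.gen_breath_recording("NORMAL", 120.0, 8000.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def planted_burst_recording(burst_times, burst_amps, duration_s=120.0,
                            rate=2000.0, freq=440.0):
    """Recording with pure-tone Hann bursts at known times and amplitudes."""
    n = int(duration_s * rate)
    t = np.arange(n) / rate
    x = np.zeros(n)
    w = int(rate)  # 1-s bursts
    env = np.hanning(w)
    for tc, amp in zip(burst_times, burst_amps):
        i0 = int(tc * rate) - w // 2
        x[i0 : i0 + w] += amp * env * np.sin(2 * np.pi * freq * t[i0 : i0 + w])
    return sasod.BreathRecording(samples=np.clip(x, -1, 1), rate=rate,
                                 subject_id="planted")
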