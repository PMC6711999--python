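import numpy as np
import pytest
from hypothesis import settings

import tfpac as tp

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def coupled_signal():
    """Noisy coupled-sinusoid record used across tests (chi=0.2, 6 dB)."""
    spec = tp.SinusoidalPACSpec(f_p=10.0, f_a=60.0, chi=0.2, fs=1000.0,
                                duration=2.0, snr_db=6.0, seed=3)
    return spec, tp.generate_dataset1(spec)


@pytest.fixture(scope="session")
def tone_tfd():
    """Plain Rihaczek surface of a 10 Hz analytic tone."""
    fs, n = 200.0, 400
    t = np.arange(n) / fs
    sig = tp.Signal(np.exp(2j * np.pi * 10.0 * t), fs=fs)
    return sig, tp.compute_tfd(sig, tp.KernelConfig(kind="rihaczek"))
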