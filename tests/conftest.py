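import numpy as np
import pytest

from capbio import synthetic as syn

FS = 10_000.0


@pytest.fixture(scope="session")
def clean_ecg_session():
    """Noise-free 2-min resting recording with ground-truth R-times."""
    cfg = syn.ECGSimConfig(mean_hr=70.0, rr_sd=0.02, r_amp=100e-6, seed=1)
    ecg_ref, cecg, truth = syn.synth_ecg_session(cfg, duration=120.0, fs=FS)
    return ecg_ref, cecg, truth


@pytest.fixture(scope="session")
def cough_session():
    """Default seven-cycle cough-protocol session (burst RMS 10x rest)."""
    return syn.synth_cough_session(syn.ECGSimConfig(seed=0),
                                   syn.CoughSimConfig(seed=0), fs=FS)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
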