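import numpy as np
import pytest

import whiskdecode as wd


@pytest.fixture(scope="session")
def small_session():
    """A small synthetic session shared by unit tests (5 trials/class)."""
    cfg = wd.synth.desk_config(seed=11, n_per_class=5)
    rec, stim_full = wd.synth.generate_recording(cfg)
    stim, truth = wd.synth.split_truth(stim_full)
    return cfg, rec, stim, truth


@pytest.fixture(scope="session")
def small_raster(small_session):
    _, rec, _, _ = small_session
    spk = wd.preprocess.bandpass(rec, "SPIKE")
    return wd.preprocess.detect_spikes(spk)


@pytest.fixture(scope="session")
def high_snr_session():
    """High-SNR session: 30 trials/class, strong UP/DOWN rate contrast."""
    # "high SNR" here means a strong UP/DOWN firing contrast: dense UP-state
    # multi-unit activity (80 Hz/channel) against a quiescent DOWN state,
    # well above the false-crossing floor of the 3-sigma detector
    cfg = wd.synth.desk_config(
        seed=7,
        n_per_class=30,
        up_mua_rate=80.0,
        down_mua_rate=0.2,
        noise_sd=2.0,
    )
    rec, stim_full = wd.synth.generate_recording(cfg)
    stim, truth = wd.synth.split_truth(stim_full)
    return cfg, rec, stim, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
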