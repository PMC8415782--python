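import numpy as np
import pytest

from seegdecode import (
    SynthConfig,
    apply_montage,
    build_bipolar_montage,
    extract_iaf,
    simulate_recording,
)


@pytest.fixture(scope="session")
def small_sim():
    """A fast single-lead session: 2 classes x 8 trials at 1 kHz."""
    cfg = SynthConfig(
        seed=1,
        n_leads=1,
        trials_per_class=8,
        sampling_rate=1000.0,
        effect_size=4.0,
        amplitude_jitter_cv=0.2,
    )
    recording, events, truth = simulate_recording(cfg)
    return cfg, recording, events, truth


@pytest.fixture(scope="session")
def small_iaf(small_sim):
    _, recording, events, truth = small_sim
    bipolar = apply_montage(recording, build_bipolar_montage(recording))
    return extract_iaf(bipolar), events, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
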