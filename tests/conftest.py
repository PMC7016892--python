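import numpy as np
import pytest

from lfposc.containers import MultiChannelRecording
from lfposc.synth import SynthConfig, generate_lfp

#: band fractions summing to 1 (no broadband remainder), used wherever a
#: test needs the injected fractions to be exactly identifiable
SUM1_FRACTIONS = {
    "SO": 0.55, "delta": 0.17, "theta": 0.09, "beta": 0.06,
    "slow-gamma": 0.05, "fast-gamma": 0.04, "epsilon": 0.04,
}


@pytest.fixture(scope="session")
def ladder_recording():
    """Six-channel 300 s session with a known SO lead ladder and PAC."""
    cfg = SynthConfig(
        n_channels=6, duration=300.0, rate=500.0,
        band_power_fractions=dict(SUM1_FRACTIONS),
        so_lag_per_channel=[0.0, 10.0, 25.0, 40.0, 70.0, 100.0],
        pac_depth={("SO", "fast-gamma"): 0.6}, seed=101,
    )
    rec, truth = generate_lfp(cfg)
    return cfg, rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_recording(samples, rate=500.0):
    samples = np.atleast_2d(np.asarray(samples, float))
    depths = 2300.0 - 100.0 * np.arange(samples.shape[0])
    return MultiChannelRecording(samples, rate, depths)
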