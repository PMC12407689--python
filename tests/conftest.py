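import numpy as np
import pytest

from flywaggle import synth


@pytest.fixture(scope="session")
def small_config():
    """A one-minute default-noise synthetic recording configuration."""
    return synth.SynthConfig(duration_s=60.0, seed=11)


@pytest.fixture(scope="session")
def small_recording(small_config):
    """(meta, tracks, audio, truth) for the one-minute recording."""
    truth = synth.sample_ethogram(small_config)
    return synth.render_recording(small_config, truth)


@pytest.fixture(scope="session")
def clean_config():
    """A noise-free, dropout-free configuration for construction oracles."""
    return synth.SynthConfig.from_dict(
        {
            **synth.SynthConfig(duration_s=60.0, seed=5).to_dict(),
            "track_noise_mm": 0.0,
            "wing_noise_deg": 0.0,
            "baseline_wing_deg_sd": 0.0,
            "wingtip_dropout": 0.0,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
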