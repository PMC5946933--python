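import numpy as np
import pytest

from grainacoustics.profiles import default_profiles
from grainacoustics.simulate import AcousticScenario, generate_recording


@pytest.fixture(scope="session")
def profiles():
    """The two bundled synthetic spectral profiles."""
    return default_profiles()


@pytest.fixture(scope="session")
def standard_scene():
    """A 60-s scene at the default detection SNR of 10 (peak 0.5 over
    noise RMS 0.05), with distractors present."""
    scenario = AcousticScenario(
        duration=60.0, burst_rate=0.15, distractor_rate=0.1, rng_seed=11
    )
    waveform, truth = generate_recording(scenario)
    return scenario, waveform, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
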