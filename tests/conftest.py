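import numpy as np
import pytest

from dyadssvep import AnalysisParams, SynthConfig, build_montage, generate_schedule


@pytest.fixture(scope="session")
def montage():
    return build_montage("smarting24")


@pytest.fixture(scope="session")
def params():
    return AnalysisParams()


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(rng_seed=123)


@pytest.fixture(scope="session")
def short_schedule():
    """Reduced session (12 images) for fast structural tests."""
    return generate_schedule(n_images=3, reps_per_block=2, n_blocks=2, rng_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def quiet_config():
    """Low-noise generator for checks that need a clean evoked response."""
    return SynthConfig(noise_rms=2.0, rng_seed=5)
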