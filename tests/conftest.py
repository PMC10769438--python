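import numpy as np
import pytest

from bitescape import CalibrationScale, GeneratorConfig, generate_dataset

PX_PER_MM = 10.0


@pytest.fixture(scope="session")
def scale():
    return CalibrationScale(px_per_mm=PX_PER_MM, session_id="test")


@pytest.fixture(scope="session")
def noiseless_config():
    return GeneratorConfig(
        n_individuals=2,
        strikes_per_individual=4,
        landmark_jitter_px=0.0,
        dropout_rate=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    return generate_dataset(noiseless_config, seed=11)


@pytest.fixture(scope="session")
def default_dataset():
    """Default study conditions: 4 species x 5 individuals x 8 strikes."""
    return generate_dataset(GeneratorConfig(), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
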