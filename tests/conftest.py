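import numpy as np
import pytest

from dyadsync.fitting import GAConfig
from dyadsync.synth import GeneratorConfig


@pytest.fixture(scope="session")
def ga_small() -> GAConfig:
    """Reduced evolutionary-search budget for test-scale fitting."""
    return GAConfig(population_size=24, generations=25, patience=8)


@pytest.fixture()
def gen_config() -> GeneratorConfig:
    return GeneratorConfig(seed=1234)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(98765)
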