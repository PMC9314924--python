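import numpy as np
import pytest

from camoevolve.imagega import GAConfig, init_population
from camoevolve.pattern_animal import ANIMAL_TAGS, build_rd_gamut


@pytest.fixture(scope="session")
def small_gamut():
    """Reduced-size reaction-diffusion gamut shared across the suite."""
    return build_rd_gamut(resolution=96, iterations=1200, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def animal_pop():
    cfg = GAConfig(seed=3)
    return init_population(cfg, ANIMAL_TAGS)
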