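import numpy as np
import pytest

from pa2c.simulate import GeneratorConfig, make_family


@pytest.fixture(scope="session")
def default_family():
    """One seeded synthetic family (8 per clade, default mutation rate)."""
    return make_family(GeneratorConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
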