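import numpy as np
import pytest

from sexbias.synthdata import SynthConfig, generate_annotation, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A compact but fully consistent two-group synthetic scenario."""
    return generate_world(SynthConfig(n_mirnas=300), groups=("Infectious", "Neoplasms"), seed=11)


@pytest.fixture(scope="session")
def small_annotation():
    return generate_annotation(60, n_chromosomes=5, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
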