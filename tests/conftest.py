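import numpy as np
import pytest

from ratiotrait import GeneticParams, PopulationDesign


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def default_params():
    """Standard parameterization: means 10, unit variances."""
    return GeneticParams(mu1=10.0, mu2=10.0, h2_1=0.3, h2_2=0.3, r_g=0.0, r_e=0.0)


@pytest.fixture
def small_design():
    """A population small enough for per-test simulation."""
    return PopulationDesign(n_sires=200, dams_per_sire=10, offspring_per_dam=2, seed=7)
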