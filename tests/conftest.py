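import numpy as np
import pytest

from asbfoot import SimConfig
from asbfoot.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 24-site read-level synthetic bundle shared by pipeline-level tests."""
    outdir = tmp_path_factory.mktemp("simdata")
    return simulate_dataset(SimConfig(n_sites=24, fraction_asb=0.25, seed=7),
                            str(outdir))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
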