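import numpy as np
import pytest

from metabostate.params import baseline_parameters, default_solver
from metabostate.scoring import GeneSets


@pytest.fixture(scope="session")
def baseline():
    return baseline_parameters()


@pytest.fixture(scope="session")
def solver():
    return default_solver()


@pytest.fixture(scope="session")
def gene_sets():
    return GeneSets.from_gmt()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
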