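import numpy as np
import pytest

from nanotx.microenv import Grid
from nanotx.nano import NPDesign


@pytest.fixture
def grid():
    return Grid(400.0, 400.0, dx=20.0)


@pytest.fixture
def small_grid():
    return Grid(100.0, 100.0, dx=20.0)


@pytest.fixture
def design():
    return NPDesign()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
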