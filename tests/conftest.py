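import numpy as np
import pytest

from teres import WeibullFit

#: Weibull used throughout the worked examples: scale 12.89 y, shape 3.75
EXAMPLE_SCALE = 12.89
EXAMPLE_SHAPE = 3.75


@pytest.fixture
def example_fit() -> WeibullFit:
    return WeibullFit(scale=EXAMPLE_SCALE, shape=EXAMPLE_SHAPE)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
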