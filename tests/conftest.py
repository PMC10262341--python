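import numpy as np
import pytest

from swalloc import DesignSpec


@pytest.fixture
def spec4() -> DesignSpec:
    """The worked-example design: four sequences, rho = 0.4, no attrition."""
    return DesignSpec(J=4, rho=0.4, r=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230)
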