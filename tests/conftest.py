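import numpy as np
import pytest

from paddyfield.param_space import ParameterSpec


@pytest.fixture
def unit_specs():
    """Two continuous dimensions on [0, 1] with 0.01 sow resolution."""
    return [
        ParameterSpec(
            name=n, lower=0.0, upper=1.0,
            init_range=(0.0, 1.0), init_resolution=0.01,
        )
        for n in ("x", "y")
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
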