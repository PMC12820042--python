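import numpy as np
import pytest

from intersep.design import build_design


@pytest.fixture(scope="session")
def desk_design():
    """Small design matching the default simulation profile."""
    return build_design(6, 5, 100.0, 8, seed=0)


@pytest.fixture(scope="session")
def paper_scale_design():
    """The acquisition-scale design: 24 triads, 5 repetitions, 62 channels."""
    return build_design(24, 5, 500.0, 62, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
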