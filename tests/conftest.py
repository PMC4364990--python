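import numpy as np
import pytest

from emosim.config import RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def world():
    from emosim.world import WorldConfig

    return WorldConfig()


@pytest.fixture
def tiny_cfg():
    """A 1-day burn-in, one-interval recording window (fast engine runs)."""
    return RunConfig(burn_in=720.0, run_length=2520.0, record_window=2520.0)


@pytest.fixture
def default_doms20():
    from emosim.config import default_doms

    return np.asarray(default_doms(20))
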