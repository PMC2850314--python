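import numpy as np
import pytest

from symdet.model import (
    CONDITIONS,
    CUED,
    HIGH,
    LOW,
    NONCUED,
    ChannelParams,
    Condition,
    TABLE1_PARAMS,
)


@pytest.fixture
def cc_params() -> ChannelParams:
    return TABLE1_PARAMS["CC"]


@pytest.fixture
def cued_high() -> Condition:
    return Condition(CUED, HIGH)


@pytest.fixture
def noncued_high() -> Condition:
    return Condition(NONCUED, HIGH)


@pytest.fixture
def uniform_params() -> ChannelParams:
    """Parameters identical across cue and salience, with a noise-
    sensitive excitatory path so control responses are substantial."""
    return ChannelParams(
        s_et={(CUED, HIGH): 1000.0, (CUED, LOW): 1000.0,
              (NONCUED, HIGH): 1000.0, (NONCUED, LOW): 1000.0},
        s_eb=800.0,
        s_it={HIGH: 100.0, LOW: 100.0},
        s_ib=500.0,
        z_prime=1.0,
        p=2.1,
    )


@pytest.fixture
def masker_grid() -> np.ndarray:
    return np.logspace(-2, -1, 8)
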