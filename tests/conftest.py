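import numpy as np
import pytest

from cscompliance import (
    DEFAULT_PARAMS,
    PhysicalParameters,
    WaveformSpec,
    generate_subject,
)


@pytest.fixture(scope="session")
def default_params() -> PhysicalParameters:
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free synthetic subject with truth spinal fraction 0.75."""
    return generate_subject(DEFAULT_PARAMS, WaveformSpec(seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
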