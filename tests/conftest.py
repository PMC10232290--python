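import numpy as np
import pytest

from pedcm.microcircuit import MicrocircuitParameters
from pedcm.synthetic import default_base_params


@pytest.fixture(scope="session")
def params() -> MicrocircuitParameters:
    """Default microcircuit (no condition effects)."""
    return MicrocircuitParameters()


@pytest.fixture(scope="session")
def base_params() -> MicrocircuitParameters:
    """Cohort base circuit: default constants + condition log-gains."""
    return default_base_params()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
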