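import numpy as np
import pytest

from carokin import KineticParameters, build_network
from carokin.synth import preset_assay


@pytest.fixture
def network4():
    return build_network(4)


@pytest.fixture
def params4():
    return KineticParameters(
        k_f=[0.5, 0.5, 0.5, 0.5, 0.5],
        k_r=[5.0, 5.0, 5.0, 5.0, 5.0],
        k_cat=[0.05, 0.04, 0.03, 0.02],
    )


@pytest.fixture
def dense_assay():
    return preset_assay("dense_schedule")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
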