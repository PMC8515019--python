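import numpy as np
import pytest

from qutece_bbb.signal_model import AcquisitionParams, ContrastAgentParams
from qutece_bbb.synthetic_data import PhantomSpec, build_atlas, simulate_cohort

#: noise level giving SNR ~ 10 on brain tissue at the default signal scale
SNR10_SIGMA = 2.4


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def agent():
    return ContrastAgentParams()


@pytest.fixture(scope="session")
def small_spec():
    """Small, fast, fully clean phantom spec (no noise/bias/motion)."""
    return PhantomSpec(grid_size=32, n_regions=4, seed=11)


@pytest.fixture(scope="session")
def small_atlas(small_spec):
    return build_atlas(small_spec)


@pytest.fixture(scope="session")
def clean_cohort(small_spec):
    """One clean subject, one leaking region, all four days."""
    return simulate_cohort(
        small_spec,
        1,
        {"baseline": 0.0, "hit1": 0.002, "hit2": 0.004, "hit3": 0.008},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
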