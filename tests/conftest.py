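import numpy as np
import pytest

import nmala as nm
from nmala.simulate import TopologySpec, simulate_network


@pytest.fixture(scope="session")
def smoking():
    return nm.load_smoking()


@pytest.fixture(scope="session")
def toy_net():
    """The worked 3-trial network: one 3-arm {1,2,3}, plus {1,2} and {1,3}."""
    return nm.make_toy_fixture("toy_s23")


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated consistency network (6 trials, 3 treatments)."""
    ts = TopologySpec(
        designs=[((1, 2), 2), ((1, 3), 2), ((2, 3), 2)],
        family="binomial",
        d={2: 0.6, 3: -0.4},
        tau=0.3,
        mu_sd=0.7,
        arm_size=200,
        seed=20231,
    )
    return simulate_network(ts)


@pytest.fixture(scope="session")
def smoking_consistency_fit(smoking):
    return nm.fit(nm.ModelSpec("consistency", "binomial"), smoking)


@pytest.fixture(scope="session")
def smoking_jackson_fit(smoking):
    return nm.fit(nm.ModelSpec("jackson", "binomial"), smoking)
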