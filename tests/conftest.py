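import numpy as np
import pytest

from flpswitch import (MechanisticParameters, ReducedParameters,
                       build_mechanistic_network)
from flpswitch.synthetic import default_truth


@pytest.fixture(scope="session")
def mech_params() -> MechanisticParameters:
    return MechanisticParameters(
        alpha_a=0.9, alpha_b=0.2, beta_p=0.03, beta_d=0.7, K_a=0.9, K_b=0.25,
        pairA_k_on=0.5, pairA_k_off=0.3, pairA_m1=0.5, pairA_m2=0.5,
        pairB_k_on=0.4, pairB_k_off=0.25, pairB_m1=0.4, pairB_m2=0.6,
        k3=0.5, k3_rev=0.2, k4=0.5, k4_rev=0.2, k5=0.5, k5_rev=0.2,
        k6=0.5, k6_rev=0.2, k7=0.5, k7_rev=0.2, k8=0.5, k8_rev=0.1,
        delta=0.15, alpha_d=1.0)


@pytest.fixture(scope="session")
def network(mech_params):
    return build_mechanistic_network(mech_params)


@pytest.fixture(scope="session")
def truth() -> ReducedParameters:
    return default_truth()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)
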