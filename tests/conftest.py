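import numpy as np
import pytest

from cav3ephys.constructs import construct_params
from cav3ephys.protocols import (
    iv_activation_protocol,
    kinetics_protocol,
    ssi_protocol,
)
from cav3ephys.simulate import simulate_recording


@pytest.fixture(scope="session")
def wt():
    return construct_params("WT")


@pytest.fixture(scope="session")
def q1158h():
    return construct_params("Q1158H")


@pytest.fixture(scope="session")
def wt_iv_noiseless(wt):
    return simulate_recording(wt, iv_activation_protocol(), noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def wt_ssi_noiseless(wt):
    return simulate_recording(wt, ssi_protocol(), noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def wt_kinetics_noiseless(wt):
    return simulate_recording(wt, kinetics_protocol(), noise_sd=0.0, seed=1)

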