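"""Shared fixtures: ground truths, synthetic datasets, validation curves."""

import numpy as np
import pytest
from hypothesis import settings

import pronyfit as pf

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ogden():
    return pf.DEFAULT_OGDEN


@pytest.fixture(scope="session")
def truth_n1():
    return pf.GroundTruth(prony=pf.PronySeries(g=[0.4], tau=[0.1]))


@pytest.fixture(scope="session")
def truth_n3():
    return pf.default_truth()


@pytest.fixture(scope="session")
def data_n1(truth_n1):
    return pf.make_dma_dataset(truth_n1, rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def data_n3(truth_n3):
    return pf.make_dma_dataset(truth_n3, rng=np.random.default_rng(1))


@pytest.fixture(scope="session")
def validation_n1(truth_n1):
    """(ramp replicates, loop, fitted curves) from the noiseless N=1 truth."""
    ramps, loop = pf.make_validation_series(truth_n1, disp_noise_frac=0.0,
                                            rng=np.random.default_rng(2))
    curves = pf.build_validation_curves(ramps, loop)
    return ramps, loop, curves


@pytest.fixture(scope="session")
def sim_settings(ogden):
    return pf.SimulationSettings(ogden=ogden)
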