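import numpy as np
import pytest

from ecvagree import RegionSpec, ScenarioConfig, generate


@pytest.fixture(scope="session")
def linked_noisefree():
    """Zero-noise, zero-uncertainty physically linked scenario.

    Every true change is 100%-confident and FAPAR is a strictly
    increasing function of LAI, so all simultaneous changes fall on the
    contingency diagonal.
    """
    sc = ScenarioConfig(seed=11, ny=16, nx=16, n_years=2,
                        noise_scale=0.0, uncertainty_scale=0.0)
    return generate(sc)


@pytest.fixture(scope="session")
def noisy_default():
    """Default retrieval-archetype scenario with observation noise."""
    sc = ScenarioConfig(seed=23, ny=16, nx=16, n_years=3)
    return generate(sc)


@pytest.fixture
def full_region():
    def make(stack):
        return RegionSpec("all", np.ones(stack.shape[1:], dtype=bool))
    return make
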