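import numpy as np
import pytest

from cxrcad import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def nodule_phantom():
    """One deterministic nodule phantom with mask and label."""
    return generate_phantom(PhantomSpec(seed=7, with_nodule=True))


@pytest.fixture(scope="session")
def normal_phantom():
    return generate_phantom(PhantomSpec(seed=7, with_nodule=False))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
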