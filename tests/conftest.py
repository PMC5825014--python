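import numpy as np
import pytest

from spinemorph import five_spine_phantom, run


@pytest.fixture(scope="session")
def five_spine_result():
    """One segmented five-spine phantom shared by read-only tests."""
    vol, truth = five_spine_phantom(seed=1)
    return vol, truth, run(vol, truth.seeds)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
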