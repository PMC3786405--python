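import numpy as np
import pytest

import downsel as ds


@pytest.fixture(scope="session")
def constants():
    return ds.ModelConstants()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def procedural_net():
    """A freshly built six-group channel (do not mutate in tests)."""
    return ds.build_procedural(seed=0)


@pytest.fixture()
def small_net():
    """A mutable copy of the channel network for plasticity tests."""
    return ds.build_procedural(seed=0).copy()


def group_ids(net, *labels):
    return [net.group_labels.index(l) for l in labels]
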