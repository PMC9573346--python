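import numpy as np
import pytest

from palmprint import example_sets


@pytest.fixture(scope="session")
def sets():
    """The shipped example PSSM sets (4 groups, one RT)."""
    return example_sets()


@pytest.fixture(scope="session")
def non_rt_sets(sets):
    return [s for s in sets if not s.is_rt]


@pytest.fixture(scope="session")
def rt_set(sets):
    return next(s for s in sets if s.is_rt)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
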