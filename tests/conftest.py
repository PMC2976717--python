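import numpy as np
import pytest

from neolith import fixtures
from neolith.haplotypes import TRIMMED_WINDOW, synthetic_reference


@pytest.fixture(scope="session")
def derenburg():
    """The embedded graveyard sample (26 individuals)."""
    return fixtures.derenburg_table1()


@pytest.fixture(scope="session")
def derenburg22(derenburg):
    """The 22 haplotype-bearing members."""
    return derenburg.with_haplotypes()


@pytest.fixture(scope="session")
def reference():
    """Synthetic reference over the trimmed window (297 sites)."""
    return synthetic_reference(TRIMMED_WINDOW)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
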