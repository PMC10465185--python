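import numpy as np
import pytest

from nkassay import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_config():
    """Two donors (one per assay day), small populations — fast unit runs."""
    return SimConfig(n_donors=2, day_assignment=(2.5, 3.5),
                     cells_per_population=2000, seed=1)
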