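import numpy as np
import pytest

from pursuitcspk.synthetic import paper_like_config, simulate_session


@pytest.fixture(scope="session")
def tiny_session():
    """Small but complete synthetic session shared by read-only tests."""
    return simulate_session(paper_like_config(n_cells=2, n_trials=3, master_seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
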