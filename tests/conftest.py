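import numpy as np
import pytest
from hypothesis import settings

import paleoniche as pn

settings.register_profile("ci", derandomize=True, max_examples=200,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic system without niche evolution (bm_rate=0)."""
    return pn.make_world(n_species=4, n_rows=20, n_cols=20, n_slices=20,
                         n_occ=1000, n_fossils=25, seed=11)


@pytest.fixture(scope="session")
def evolving_world():
    """A synthetic system with Brownian niche evolution."""
    return pn.make_world(n_species=6, n_rows=25, n_cols=25, n_slices=30,
                         n_occ=80, n_fossils=20, bm_rate=0.5, seed=23)


@pytest.fixture(scope="session")
def small_results(small_world):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pn.PPGM.from_world(small_world).fit()


@pytest.fixture(scope="session")
def evolving_results(evolving_world):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pn.PPGM.from_world(evolving_world).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
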