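import numpy as np
import pytest
from hypothesis import settings

import cleavekit as ck

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel():
    """6 proteases, 3 families, one private-motif protease."""
    return ck.build_panel(M=6, L=10, n_families=3, seed=11, noise_sd=0.5)


@pytest.fixture(scope="session")
def small_library(small_panel):
    lib, truth = ck.simulate_library(small_panel, 600, motif_fraction=0.3,
                                     seed=12, return_truth=True)
    return lib, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_peptides(rng, n, L=10):
    idx = rng.integers(0, 20, size=(n, L))
    return ["".join(ck.AMINO_ACIDS[i] for i in row) for row in idx]
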