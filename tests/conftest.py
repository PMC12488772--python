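import numpy as np
import pytest

from ucbridge import simdata


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic bridging study shared across tests.

    4 recipients x 4 donors, 8 connected families of 24-32 individuals,
    3 chromosomes x 40 markers, one polygenic trait at h2 = 0.5.
    """
    return simdata.simulate_study(
        n_chromosomes=3,
        chromosome_length=1.5,
        markers_per_chromosome=40,
        n_recipients=4,
        n_donors=4,
        n_families=8,
        family_size_range=(24, 32),
        traits={"trait1": {"heritability": 0.5, "effect_sd": 0.1}},
        seed=20240917,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
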