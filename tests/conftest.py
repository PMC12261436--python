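import numpy as np
import pytest

from grackle import simulation as sim


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by evaluation tests (pure function of seed)."""
    return sim.simulate_cohort(
        n_genes=120, n_samples=40, n_subgroups=4, target_modules=8,
        iter_range=(80, 120), seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
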