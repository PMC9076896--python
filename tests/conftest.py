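import numpy as np
import pytest

from rangecoex import synthetic as syn
from rangecoex import vital_rates as vr


@pytest.fixture(scope="session")
def small_pool():
    return syn.generate_species_pool(2, 2, "range_limited", 5)


@pytest.fixture(scope="session")
def small_dataset(small_pool):
    design = syn.ExperimentDesign(n_individuals_per_treatment=40, rng_seed=7)
    return syn.simulate_individuals(small_pool, design)


@pytest.fixture(scope="session")
def fitted_demog(small_dataset):
    return vr.fit_demography(small_dataset.records, small_dataset.recruitment_trials)


@pytest.fixture(scope="session")
def origins(small_pool):
    return {s.species_id: s.origin for s in small_pool}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
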