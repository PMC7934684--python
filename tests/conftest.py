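import numpy as np
import pytest

import conchmorph as cm


@pytest.fixture(scope="session")
def study_spec():
    """The default study design: 12 species (5 truncated A, 7 accelerated B),
    6 specimens each, landmark noise 0.02 x stage centroid size."""
    return cm.default_study_spec(seed=11, n_specimens=6, noise_sd=0.02)


@pytest.fixture(scope="session")
def study_dataset(study_spec):
    return cm.simulate_dataset(study_spec)


@pytest.fixture(scope="session")
def study_result(study_dataset):
    """One full pipeline run on the study dataset (199 permutations)."""
    return cm.run_pipeline(
        cm.RunConfig(seed=11, permutation_iterations=199), dataset=study_dataset
    )


@pytest.fixture(scope="session")
def small_spec():
    base = cm.default_study_spec(seed=7)
    models = base.species_models[:2] + base.species_models[5:7]
    return cm.SimulationSpec(models, n_specimens=2, noise_sd=0.01, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return cm.simulate_dataset(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
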