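import numpy as np
import pytest

from darkbirds import data_prep, fossil_model, synthetic


@pytest.fixture(scope="session")
def arch_dataset():
    """Default 69-archipelago synthetic dataset with its ground truth."""
    return synthetic.generate_archipelago_dataset(seed=11)


@pytest.fixture(scope="session")
def design(arch_dataset):
    arch, _ = arch_dataset
    retained, _ = data_prep.screen_collinearity(arch)
    return data_prep.prepare_design(arch, retained, synthetic.DEFAULT_TRANSFORMS)


@pytest.fixture(scope="session")
def lm_fit(arch_dataset, design):
    arch, _ = arch_dataset
    return fossil_model.fit_fossil_lm(design, arch["n_fossil"])


@pytest.fixture(scope="session")
def grid_dataset(arch_dataset):
    arch, _ = arch_dataset
    return synthetic.generate_grid_dataset(
        nx=15, ny=15, archipelago_ids=list(arch["archipelago_id"]), seed=12
    )


@pytest.fixture(scope="session")
def species_register(arch_dataset):
    arch, _ = arch_dataset
    return synthetic.generate_species_register(arch, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
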