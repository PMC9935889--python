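import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import magbias as mb

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalog():
    """Small module catalog shared across tests."""
    return mb.generate_catalog(30, mb.poisson_steps(6.0), seed=101)


@pytest.fixture(scope="session")
def parametric_model(catalog):
    return mb.sample_parametric_model(catalog, seed=202)


@pytest.fixture(scope="session")
def parametric_matrix(catalog, parametric_model):
    """Fullness matrix drawn from a known logit-linear truth (400 genomes)."""
    return mb.generate_parametric_dataset(parametric_model, catalog, 400, seed=303)


@pytest.fixture(scope="session")
def module_fits(parametric_matrix):
    return mb.fit_all_modules(parametric_matrix)


@pytest.fixture(scope="session")
def slope_table(module_fits, catalog):
    return mb.extract_slopes(module_fits.values(), catalog)


@pytest.fixture(scope="session")
def complete_genomes(catalog):
    rng = np.random.default_rng(404)
    return [
        mb.generate_complete_genome(
            f"mock{i + 1}", mb.DEFAULT_PHYLA[i % 4], catalog, n_contigs=200, seed=rng
        )
        for i in range(8)
    ]
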