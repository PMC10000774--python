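import numpy as np
import pytest

from chromaqbd import anova_table, fit_response_model, fit_statistics, synthetic


@pytest.fixture(scope="session")
def screening_factors():
    return synthetic.screening_factors()


@pytest.fixture(scope="session")
def demo_table():
    """Triplicated synthetic screening study (8 corners + 3 centers, x3)."""
    return synthetic.demo_response_table(n_center=3, n_replicates=3, seed=11)


@pytest.fixture(scope="session")
def fitted_models(demo_table):
    models = {}
    for cma in demo_table.cma_names:
        m = fit_response_model(demo_table, cma)
        anova_table(m, demo_table)
        fit_statistics(m, demo_table)
        models[cma] = m
    return models


@pytest.fixture(scope="session")
def table5():
    return synthetic.table5_response_table()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
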