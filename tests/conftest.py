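import numpy as np
import pytest

from tensorreg import MultinomialTensorRegression
from tensorreg.synthetic import SyntheticScenario, generate


@pytest.fixture(scope="session")
def default_scenario():
    """The reference study conditions: 20x24x20 volumes, 3 classes,
    100 subjects per class, planted rank-1 signals at SNR 6."""
    return SyntheticScenario()


@pytest.fixture(scope="session")
def default_fit(default_scenario):
    """One fit of the default planted scenario, shared across tests.

    Returns (data, true_params, model, results).
    """
    data, truth = generate(default_scenario)
    model = MultinomialTensorRegression(data)
    results = model.fit(seed=11)
    return data, truth, model, results


@pytest.fixture(scope="session")
def small_planted():
    """Desk-scale separable dataset for fast estimation tests."""
    scenario = SyntheticScenario(shape=(8, 9, 8), n_per_class=20, seed=11)
    data, truth = generate(scenario)
    return scenario, data, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
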