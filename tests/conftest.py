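"""Shared fixtures.

The expensive phased fits (cfgI/cfgX/cfgXVI on the standard synthetic
bundle) are session-scoped so unit, property and acceptance tests reuse
them instead of refitting.
"""

import numpy as np
import pytest

from krillassess.config import preset
from krillassess.core import ModelStructure, ParameterSet
from krillassess.estimation import run_replicates
from krillassess.synth import default_scenario, observe, simulate_truth


@pytest.fixture(scope="session")
def structure():
    return ModelStructure()


@pytest.fixture(scope="session")
def scenario(structure):
    return default_scenario(structure, seed=1)


@pytest.fixture(scope="session")
def truth_and_trajectory(scenario):
    return simulate_truth(scenario, np.random.default_rng(scenario.seed))


@pytest.fixture(scope="session")
def bundle(scenario, truth_and_trajectory):
    _, trajectory = truth_and_trajectory
    return observe(trajectory, scenario, np.random.default_rng(scenario.seed + 1))


def _best_fit(name, bundle, seed=3):
    fits, summary = run_replicates(
        preset(name, max_reorderings=2), bundle, n_replicates=1, seed=seed
    )
    return fits[summary.best_index]


@pytest.fixture(scope="session")
def fit_cfgI(bundle):
    return _best_fit("cfgI", bundle)


@pytest.fixture(scope="session")
def fit_cfgX(bundle):
    return _best_fit("cfgX", bundle)


@pytest.fixture(scope="session")
def fit_cfgXVI(bundle):
    return _best_fit("cfgXVI", bundle)


@pytest.fixture()
def defaults(structure):
    return ParameterSet.defaults(structure)
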