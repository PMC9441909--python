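import numpy as np
import pytest

from smdsnet.polychoric import estimate_summary
from smdsnet.simulate import (
    SMDS_LOADINGS,
    SMDS_THRESHOLDS,
    simulate_onefactor,
)


@pytest.fixture(scope="session")
def table_params():
    """Generating loadings and thresholds for the nine symptom items."""
    return SMDS_LOADINGS.copy(), SMDS_THRESHOLDS.copy()


@pytest.fixture(scope="session")
def onefactor_data():
    """One medium one-factor sample, shared across tests."""
    return simulate_onefactor(n=13377, seed=20240501)


@pytest.fixture(scope="session")
def onefactor_summary(onefactor_data):
    return estimate_summary(onefactor_data.values, [2] * 9,
                            onefactor_data.item_names)


@pytest.fixture(scope="session")
def population_summary():
    """Population-exact 'observed' statistics under the generating model."""
    lam, tau = SMDS_LOADINGS, SMDS_THRESHOLDS
    rho = np.outer(lam, lam)
    np.fill_diagonal(rho, 1.0)
    big = simulate_onefactor(n=4000, seed=3)  # only for gamma scaffolding
    s = estimate_summary(big.values, [2] * 9)
    s.rho = rho
    s.thresholds = [np.array([t]) for t in tau]
    return s
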