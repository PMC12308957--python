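import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def scen2_data():
    """One moderate non-linear dataset reused across tests."""
    from dynacor.simulate import scenario_II

    return scenario_II(n=800, seed=2)


@pytest.fixture(scope="session")
def scen2_fit(scen2_data):
    """A converged full-model fit on the shared dataset."""
    from dynacor.estimation import fit_pair

    fit = fit_pair(scen2_data.y1, scen2_data.y2, scen2_data.z)
    assert fit.converged
    return fit
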