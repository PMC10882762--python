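import numpy as np
import pandas as pd
import pytest

from phc_spaceff import IndicatorPanel, SdmSpec, inverse_distance_weights, make_coordinates
from phc_spaceff.synthetic_data import SyntheticScenario, lattice_weights, simulate_indicator_panel


@pytest.fixture(scope="session")
def lattice_w31():
    return lattice_weights(31)


@pytest.fixture(scope="session")
def sdm_spec31(lattice_w31):
    return SdmSpec("y", ("x1", "x2"), lattice_w31, "unit")


@pytest.fixture(scope="session")
def small_panel():
    """12-unit, 2-year indicator panel with every pipeline column."""
    panel, _ = simulate_indicator_panel(SyntheticScenario(N=12, T=2, seed=99))
    return panel


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_tidy_panel(n_units=4, n_years=2, indicators=("a", "b"), seed=0):
    rng = np.random.default_rng(seed)
    rows = [
        {"unit_id": f"u{i}", "year": 2000 + t, "indicator": ind, "value": rng.uniform(1, 9)}
        for i in range(n_units)
        for t in range(n_years)
        for ind in indicators
    ]
    return IndicatorPanel(pd.DataFrame(rows))
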