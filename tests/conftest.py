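import numpy as np
import pandas as pd
import pytest

from runequity.synthetic import fixture_dataset


@pytest.fixture(scope="session")
def fixture_data():
    """Miniature synthetic bundle: 50 areas, 24 months, 4 events."""
    return fixture_dataset(seed=1234)


@pytest.fixture()
def tiny_areas():
    """Five handmade areas with simple covariates."""
    return pd.DataFrame(
        {
            "area_id": [f"A{i}" for i in range(5)],
            "lat": [52.1, 52.3, 52.5, 52.7, 52.9],
            "lon": [-2.0, -1.8, -1.6, -1.4, -1.2],
            "imd_score": [5.0, 15.0, 25.0, 35.0, 45.0],
            "total_pop": [1500, 1600, 1700, 1800, 1900],
            "ethnic_density": [2.0, 5.0, 10.0, 20.0, 40.0],
            "pop_density": [500.0, 1500.0, 3000.0, 5000.0, 8000.0],
            "urban_flag": [False, False, True, True, True],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
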