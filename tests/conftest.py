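import numpy as np
import pandas as pd
import pytest

from shorepop.growth import GrowthParams
from shorepop.simulate import default_config, simulate_population


@pytest.fixture(scope="session")
def west_params() -> GrowthParams:
    """West-shore seasonal growth parameters of the study system."""
    return GrowthParams(Linf=65.25, K=0.12, t0=0.52, C=0.42, ts=0.56)


@pytest.fixture(scope="session")
def sim_dataset():
    """One full synthetic two-shore dataset (fixed seed, shared read-only)."""
    return simulate_population(default_config(11), seed=11)


@pytest.fixture()
def individuals_df():
    """Tiny hand-built individual table."""
    return pd.DataFrame({
        "quadrat_id": ["q1"] * 5,
        "sl_mm": [0.8, 1.07, 10.0, 20.0, 30.0],
        "tww_g": [np.nan, 0.001, 0.1, 0.9, 2.7],
        "fww_g": [np.nan] * 5,
        "fdw_g": [np.nan, np.nan, 0.01, 0.09, 0.27],
        "sex": ["unknown", "unknown", "F", "M", "F"],
        "stage": ["unknown"] * 5,
    })
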