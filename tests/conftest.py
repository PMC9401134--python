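import warnings

import numpy as np
import pandas as pd
import pytest

from smokecast.basis import SmoothTerm
from smokecast.gam import ModelFormula
from smokecast.predictors import assemble_table
from smokecast.synthetic import SimulationConfig, generate_dataset

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated study shared across tests."""
    return generate_dataset(SimulationConfig(n_days=150, seed=42))


@pytest.fixture(scope="session")
def model_table(small_dataset):
    ds = small_dataset
    return assemble_table(ds.pm_hourly, ds.weather, ds.fire_days)


@pytest.fixture(scope="session")
def gamma_sim():
    """Simple 2-predictor Gamma regression data with known smooth truth."""
    rng = np.random.default_rng(7)
    n = 500
    x1 = rng.uniform(0.0, 1.0, n)
    x2 = rng.uniform(-2.0, 2.0, n)
    eta = 1.0 + 0.8 * np.sin(2.0 * np.pi * x1) + 0.3 * x2
    y = rng.gamma(8.0, np.exp(eta) / 8.0)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2, "eta_true": eta})


@pytest.fixture(scope="session")
def gamma_sim_formula():
    return ModelFormula("y", (SmoothTerm(("x1",), basis_dim=8), SmoothTerm(("x2",), basis_dim=8)))
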