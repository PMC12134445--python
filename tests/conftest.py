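import numpy as np
import pandas as pd
import pytest

from thermoscale import SimulationConfig, ThermalConstants, generate_species_pool


@pytest.fixture(scope="session")
def constants():
    return ThermalConstants()


@pytest.fixture(scope="session")
def noiseless_pool():
    """37 species, zero noise: every estimator must recover exactly."""
    config = SimulationConfig(n_species=37, noise_sigma=0.0, seed=11)
    return generate_species_pool(config), config


@pytest.fixture
def toy_paired_csv(tmp_path):
    """Three well-formed species pairs in the canonical schema."""
    df = pd.DataFrame({
        "species": ["a", "b", "c"],
        "ta_low": [5.0, 10.0, 15.0],
        "tc_low": [30.0, 33.0, 36.0],
        "ta_high": [15.0, 20.0, 25.0],
        "tc_high": [32.0, 35.0, 38.0],
        "heating_rate": [0.1, 0.5, 1.0],
    })
    path = tmp_path / "paired.csv"
    df.to_csv(path, index=False)
    return path, df


@pytest.fixture
def toy_rate_csv(tmp_path):
    """Two species x three rates in the canonical schema."""
    rows = []
    for sp, ta in (("a", 10.0), ("b", 15.0)):
        for v, tc_off in zip((0.1, 0.5, 1.0), (25.0, 27.0, 28.0)):
            rows.append({"species": sp, "ta": ta, "heating_rate": v,
                         "tc": ta + tc_off})
    df = pd.DataFrame(rows)
    path = tmp_path / "rates.csv"
    df.to_csv(path, index=False)
    return path, df


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
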