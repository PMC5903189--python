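import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BASE_SEED = 42


@pytest.fixture(scope="session")
def base_seed() -> int:
    return BASE_SEED


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(BASE_SEED)


@pytest.fixture(scope="session")
def default_sim_config():
    from forestcarbon.simulate import SimulationConfig

    return SimulationConfig()


@pytest.fixture(scope="session")
def outcome_dataset(default_sim_config):
    """One default draw of the subplot-outcome generator (no outliers)."""
    from forestcarbon.simulate import simulate_subplot_outcomes

    return simulate_subplot_outcomes(default_sim_config, BASE_SEED)


@pytest.fixture(scope="session")
def tree_dataset():
    """A small tree-level draw: 30 clusters, ~120 analysed subplots."""
    from forestcarbon.simulate import SimulationConfig, simulate_trees

    cfg = SimulationConfig(n_clusters=30, n_forest_land=160, n_analysed=120)
    return simulate_trees(cfg, BASE_SEED)


def toy_species() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species_code": ["A", "B"],
            "vol_a": [-9.0, -9.5],
            "vol_b": [1.75, 1.8],
            "vol_c": [1.10, 1.0],
            "wood_density_kg_m3": [600.0, 500.0],
            "hd_group": ["G1", "G1"],
        }
    )


@pytest.fixture()
def species_table() -> pd.DataFrame:
    return toy_species()
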