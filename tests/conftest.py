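import numpy as np
import pandas as pd
import pytest

from bearshield import (
    GridSpec,
    LandscapeConfig,
    StudyConfig,
    TruthConfig,
    gen_landscape,
)


@pytest.fixture(scope="session")
def small_landscape():
    """A 120x120-cell (3 x 3 km) landscape shared across tests."""
    grid = GridSpec(n_rows=120, n_cols=120)
    config = LandscapeConfig(n_habitations=12, n_roads=2, n_forest_roads=5)
    stack, features = gen_landscape(grid, config, seed=42)
    return stack, features


@pytest.fixture(scope="session")
def tiny_study_config():
    """A fast-to-simulate study: small grid, sparse fix schedule."""
    return StudyConfig(
        grid=GridSpec(n_rows=160, n_cols=160),
        landscape=LandscapeConfig(n_habitations=18, n_roads=2, n_forest_roads=6),
        truth=TruthConfig(fixes_per_day=8),
        home_radius=900.0,
    )


@pytest.fixture
def random_fixes():
    """A bear-year relocation frame from a seeded random walk."""
    rng = np.random.default_rng(7)
    n = 200
    steps = rng.normal(0.0, 30.0, size=(n, 2))
    xy = 2000.0 + np.cumsum(steps, axis=0)
    return pd.DataFrame(
        {
            "timestamp": pd.date_range("2008-05-01", periods=n, freq="30min"),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "dop": rng.uniform(1.0, 8.0, n),
        }
    )
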