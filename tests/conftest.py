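import numpy as np
import pandas as pd
import pytest

from cogage import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced cohort that keeps the full longitudinal structure."""
    return SimulationConfig(n_train=80, n_test=80, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort at the generator's default study conditions."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_pool(n: int = 184, seed: int = 5) -> pd.DataFrame:
    """Classification pool with distinct continuous scores, ages 70+."""
    r = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "age": r.uniform(70, 95, size=n).round(2),
            "cag": r.normal(0, 4, size=n),
            "em_resid": r.normal(0, 1, size=n),
            "nm_resid": r.normal(0, 1, size=n),
            "cvlt_ldfr": r.integers(4, 17, size=n).astype(float),
        }
    )
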