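import logging

import numpy as np
import pandas as pd
import pytest

from trialhte.forest import ForestConfig
from trialhte.simulate import SimulationConfig, generate_trial

logging.getLogger("trialhte").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_trial() -> pd.DataFrame:
    """One moderate default-configuration trial shared across tests."""
    return generate_trial(SimulationConfig(n=1500, seed=314))


@pytest.fixture
def tiny_forest_config() -> ForestConfig:
    """A small, fast forest configuration for structural tests."""
    return ForestConfig(num_trees=60, seed=5, ci_group_size=10,
                        center_outcomes=False)


def random_trial_frame(rng: np.random.Generator, n: int, p_bin=2, p_cont=2
                       ) -> pd.DataFrame:
    """Small ad-hoc trial table with binary outcome, mixed covariates."""
    df = pd.DataFrame({
        "patient_id": np.arange(n),
        "D": rng.integers(0, 2, n),
        "Y": rng.integers(0, 2, n),
    })
    for j in range(p_bin):
        df[f"b{j}"] = rng.integers(0, 2, n)
    for j in range(p_cont):
        df[f"c{j}"] = rng.normal(size=n)
    # both arms present in any half used by the tests
    df.loc[: n // 2, "D"] = np.tile([0, 1], n)[: n // 2 + 1]
    return df
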