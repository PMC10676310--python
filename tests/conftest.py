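import numpy as np
import pandas as pd
import pytest

from mirstab import SimulationConfig, simulate_cohort


def random_matrix(seed: int, k: int = 5, n: int = 12, base: float = 25.0,
                  spread: float = 2.0) -> pd.DataFrame:
    """Random complete-case Cp matrix with per-sample and per-assay structure."""
    rng = np.random.default_rng(seed)
    assay_means = base + rng.uniform(-3, 3, size=k)
    sample_eff = rng.normal(0, 0.8, size=n)
    values = assay_means[:, None] + sample_eff[None, :] + rng.normal(0, spread / 2, size=(k, n))
    return pd.DataFrame(
        values,
        index=[f"miR-{i + 1}" for i in range(k)],
        columns=[f"S{j + 1}" for j in range(n)],
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced cohort (16 + 16 samples) for fast file-based tests."""
    return SimulationConfig(n_hgsoc=16, n_benign=16, seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort (60 + 48) shared across tests."""
    return simulate_cohort(seed=11)
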