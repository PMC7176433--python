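import numpy as np
import pandas as pd
import pytest

from apakit.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_genes=30,
        sites_per_gene_range=(1, 4),
        n_target_genes=10,
        shift_magnitude=0.2,
        depth_per_sample=300,
        precision=100.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def sim(small_config):
    """One modest synthetic study shared across the suite."""
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def design(sim) -> pd.DataFrame:
    return sim.design


@pytest.fixture(scope="session")
def samples(design) -> list[str]:
    return design["sample"].tolist()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
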