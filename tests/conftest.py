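import numpy as np
import pandas as pd
import pytest

from xtissue.simulate import SimulationConfig, generate_intervention_cohort, generate_reference_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down study: 8 planted communities, ~300 genes."""
    return SimulationConfig(
        n_genes=300,
        community_sizes=(40, 30, 35, 20, 25, 15, 12, 20),
        n_ref_subjects_per_tissue=150,
        n_int_subjects=16,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference_cohort(small_config, seed=7)


@pytest.fixture(scope="session")
def small_intervention(small_config):
    return generate_intervention_cohort(small_config, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    """10-gene, 3-sample fixed count matrix used for TMM oracle checks."""
    data = np.array(
        [
            [120, 260, 80],
            [950, 1900, 1000],
            [40, 85, 46],
            [3000, 6200, 2800],
            [15, 28, 18],
            [480, 930, 500],
            [220, 400, 210],
            [70, 160, 65],
            [1500, 2900, 1600],
            [330, 700, 310],
        ],
        dtype=int,
    )
    return pd.DataFrame(
        data, index=[f"G{i}" for i in range(10)], columns=["A", "B", "C"]
    )
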