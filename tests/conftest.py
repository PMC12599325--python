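import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from coculture.core import CULTURE_COLUMNS, PipelineConfig, apply_detection_floor
from coculture.synthetic import default_resource_config, generate_resource_dataset

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_culture(rows) -> pd.DataFrame:
    """Rows of (focal, partner, env, replicate, density)."""
    return pd.DataFrame(rows, columns=CULTURE_COLUMNS)


def triplicate(focal, partner, env, densities):
    return [(focal, partner, env, r, d) for r, d in enumerate(densities, start=1)]


@pytest.fixture(scope="session")
def sim_dataset():
    """The default simulator study: 8 species, 32 environments, seed 1."""
    cfg = default_resource_config(seed=1)
    culture, envs = generate_resource_dataset(cfg)
    return culture, envs


@pytest.fixture(scope="session")
def sim_pipeline(sim_dataset):
    from coculture.pipeline import run_full_pipeline

    culture, envs = sim_dataset
    cfg = PipelineConfig(
        seed=1,
        chisq_iterations=20_000,
        permanova_permutations=2_000,
        enrichment_permutations=2_000,
    )
    return run_full_pipeline(culture, envs, cfg)


@pytest.fixture()
def floored_pair_culture():
    """One pair, one environment: planted facilitation of A by B and
    inhibition of B by A, noise-free."""
    rows = (
        triplicate("A", "", "glu", [1e6, 1e6, 1e6])
        + triplicate("B", "", "glu", [4e6, 4e6, 4e6])
        + triplicate("A", "B", "glu", [2e6, 2e6, 2e6])
        + triplicate("B", "A", "glu", [1e6, 1e6, 1e6])
    )
    return apply_detection_floor(make_culture(rows))
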