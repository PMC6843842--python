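import numpy as np
import pandas as pd
import pytest

from bymlogit import (
    CovariateSchema,
    MultilevelDataset,
    SimulationConfig,
    lattice_graph,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_schema():
    return CovariateSchema(
        levels={"smoke": ["never", "former", "current"], "mvpa": ["no", "yes"]},
        reference={"smoke": "never", "mvpa": "no"},
    )


@pytest.fixture
def small_dataset(small_schema, rng):
    """60 individuals in 6 areas with two categorical covariates."""
    n = 60
    df = pd.DataFrame(
        {
            "area_id": rng.choice([f"A{i}" for i in range(6)], n),
            "outcome": rng.integers(0, 2, n),
            "smoke": rng.choice(["never", "former", "current"], n),
            "mvpa": rng.choice(["no", "yes"], n),
        }
    )
    return MultilevelDataset(individuals=df, schema=small_schema)


@pytest.fixture
def path_graph():
    """5-node path: 0-1-2-3-4."""
    from bymlogit import build_graph

    ids = [f"A{i}" for i in range(5)]
    return build_graph([(ids[i], ids[i + 1]) for i in range(4)], ids)


@pytest.fixture(scope="session")
def simulated_cohort():
    """Moderate simulated cohort with spatial + iid effects and one covariate."""
    cfg = SimulationConfig(
        n_areas=36,
        mean_individuals=50,
        alpha=-1.1,
        covariate_probs={"x1": {"a": 0.5, "b": 0.5}},
        beta={"x1[b]": 0.5},
        sigma_u2=0.5,
        sigma_v2=0.1,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def grid36():
    return lattice_graph(36)
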