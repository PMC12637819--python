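import numpy as np
import pandas as pd
import pytest

from imqtl.sim import (
    PlantedEffect,
    SimulationConfig,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_study():
    """A small study with one planted interaction effect for reuse."""
    cfg = SimulationConfig(
        n_samples=400,
        n_variants=30,
        n_cpgs=8,
        cell_types=("epithelial", "stromal"),
        dirichlet_alpha=(1.0, 1.0),
        effect_table=[PlantedEffect(cpg_index=2, variant_index=10, cell_type="epithelial", beta=0.3)],
        seed=42,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    cfg = SimulationConfig(
        n_samples=300,
        n_variants=25,
        n_cpgs=6,
        cell_types=("epithelial", "stromal"),
        dirichlet_alpha=(1.0, 1.0),
        celltype_baseline_sd=0.0,
        seed=7,
    )
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_proportions(values: np.ndarray, cell_types) -> pd.DataFrame:
    samples = [f"S{i:04d}" for i in range(len(values))]
    return pd.DataFrame(values, index=pd.Index(samples, name="sample_id"), columns=list(cell_types))
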