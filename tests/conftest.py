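import numpy as np
import pandas as pd
import pytest

from desearch.datamodel import DEProfile, ExpressionExperiment
from desearch.simulate import SimulationConfig, compendium_profiles, simulate_compendium


@pytest.fixture
def tiny_experiment() -> ExpressionExperiment:
    """4 genes x 6 samples, two groups, already log scale."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(7.0, 1.0, size=(4, 6)),
        index=[f"g{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(6)],
    )
    groups = {f"s{i}": ("normal" if i < 3 else "disease") for i in range(6)}
    return ExpressionExperiment(
        "toy", values, groups, factor="disease state", is_log_scale=True
    )


@pytest.fixture(scope="session")
def small_sim():
    """Small planted-program compendium shared across test modules."""
    cfg = SimulationConfig(
        n_conditions=3,
        experiments_per_condition=3,
        n_genes=800,
        program_size=80,
        samples_per_group=5,
        seed=11,
    )
    return simulate_compendium(cfg)


@pytest.fixture(scope="session")
def small_profiles(small_sim):
    return compendium_profiles(small_sim)


def make_random_profile(
    rng: np.random.Generator,
    n: int = 300,
    profile_id: str = "p",
    space: str = "gene",
    with_pvalues: bool = True,
) -> DEProfile:
    """Unstructured noise profile with uniform p-values."""
    return DEProfile(
        profile_id=profile_id,
        space=space,
        feature_ids=np.array([f"G{i:05d}" for i in range(n)], dtype=object),
        scores=rng.normal(0, 1, n),
        pvalues=rng.uniform(0.005, 1.0, n) if with_pvalues else None,
        variances=rng.uniform(0.5, 2.0, n),
        comparison=("case", "control"),
        source_experiment=profile_id,
    )
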