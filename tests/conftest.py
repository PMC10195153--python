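import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import contevo as ce

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_dataset() -> ce.SyntheticDataset:
    """Default study-shaped synthetic dataset (65 populations)."""
    return ce.simulate_mutation_dataset(ce.SimConfig(seed=11))


def small_config(**overrides) -> ce.SimConfig:
    """A small, fast configuration for calibration-style loops."""
    base = dict(
        n_pathways=2,
        founders_per_pathway=2,
        replicates_per_founder=3,
        n_control_replicates=0,
        module_pool_size=6,
        background_pool_size=30,
        module_hit_prob=0.0,
        mutations_per_pop_mean=8.0,
        assay_replicates=0,
        extinctions={},
        seed=0,
    )
    base.update(overrides)
    return ce.SimConfig(**base)


def make_pa(table: dict[str, dict[str, int]]) -> ce.PresenceAbsenceMatrix:
    """Presence-absence matrix from a {population: {region: 0/1}} dict."""
    df = pd.DataFrame(table).T.fillna(0).astype(np.int8)
    return ce.PresenceAbsenceMatrix(
        table=df, threshold_mode="segregating", threshold=0.05
    )


def make_labeling(**pops) -> ce.GroupLabeling:
    """GroupLabeling from population=(pathway, founder) keyword pairs."""
    return ce.GroupLabeling(mapping=pops)
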