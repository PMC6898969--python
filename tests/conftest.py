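import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cortexdiff.data import ComparisonSpec, SampleSheet
from cortexdiff.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def null_dataset():
    """50-array dataset with no planted effects (global null)."""
    empty = pd.DataFrame(columns=["gene", "condition", "log2fc"])
    cfg = SimulationConfig(n_genes=2000, effects=empty, n_decoy_sets=10, seed=101)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_dataset():
    """Default dataset: TNF panels planted plus 150 random effects/condition."""
    cfg = SimulationConfig(n_genes=4000, n_extra_degs=150, seed=202)
    return generate_dataset(cfg)


@pytest.fixture
def fpos_gml_spec():
    return ComparisonSpec("FPOS_GML", "CTRL")


def two_group_sheet(n_a=10, n_b=10, group_a="FPOS_GML", group_b="CTRL"):
    """Minimal sheet with two groups only."""
    rows = [
        {"sample_id": f"A{i:02d}", "group": group_a, "case_id": f"PA{i:02d}"}
        for i in range(n_a)
    ] + [
        {"sample_id": f"B{i:02d}", "group": group_b, "case_id": f"PB{i:02d}"}
        for i in range(n_b)
    ]
    return SampleSheet(pd.DataFrame(rows))
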