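import numpy as np
import pandas as pd
import pytest

from cladescope.cladesets import CladePartition
from cladescope.synthetic import (
    CladeScenario,
    ExpressionScenario,
    ParalogScenario,
    simulate_clade_annotations,
    simulate_expression,
)


@pytest.fixture(scope="session")
def four_group_scenario():
    return CladeScenario(
        groups=("Chlorophyta", "Streptophyte_algae", "Zygnematophyceae", "Embryophyta"),
        genomes_per_group=4,
        n_families=200,
        planted_exclusives={
            frozenset({"Zygnematophyceae", "Embryophyta"}): [f"ZE{i:02d}" for i in range(12)]
        },
        dropout_rate=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def four_group_data(four_group_scenario):
    return simulate_clade_annotations(four_group_scenario)


@pytest.fixture(scope="session")
def two_module_expression():
    scenario = ExpressionScenario(
        n_genes=200,
        n_samples=60,
        modules=(
            (30, ("stress_response",), 0.9),
            (30, ("calcium_signaling",), 0.9),
        ),
        seed=7,
    )
    return simulate_expression(scenario)


@pytest.fixture
def tiny_partition():
    return CladePartition.from_mapping(
        {"g1": "A", "g2": "A", "g3": "B", "g4": "B", "g5": "C", "g6": "C"}
    )


@pytest.fixture
def random_count_matrix():
    rng = np.random.default_rng(0)
    genomes = [f"g{i}" for i in range(1, 9)]
    return pd.DataFrame(
        rng.integers(0, 3, size=(6, 8)), index=[f"f{i}" for i in range(6)], columns=genomes
    )
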