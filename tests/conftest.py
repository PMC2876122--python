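import numpy as np
import pandas as pd
import pytest

from xenomask import (
    ExpressionMatrix,
    MappingTable,
    SimulationConfig,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_clusters=40, genome_length=6000,
                            frac_homologous_clusters=0.1, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    """A 40-cluster mixed-species study shared across tests (read-only)."""
    return simulate_study(small_config)


@pytest.fixture
def toy_mapping():
    """Two clusters x two probesets x four probes, one-to-one hierarchy."""
    rows = [
        (f"p{c}{s}{k}", f"ps{c}{s}", f"tc{c}")
        for c in range(2) for s in range(2) for k in range(4)
    ]
    return MappingTable(pd.DataFrame(rows, columns=[
        "probe_id", "probeset_id", "transcript_cluster_id"]))


@pytest.fixture
def log2_matrix():
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(30, 6)),
        index=[f"tc{i:03d}" for i in range(30)],
        columns=[f"s{j}" for j in range(6)],
    )
    return ExpressionMatrix(values, "log2")
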