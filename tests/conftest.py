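import numpy as np
import pandas as pd
import pytest

from germnet.synthetic_data import SimulationConfig


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale simulation configuration reused across tests."""
    return SimulationConfig(
        seed=42,
        genome_length=12000,
        n_genes=12,
        depth_mean=30.0,
        error_rate=0.005,
        n_germline=30,
        n_somatic=10,
        ppi_nodes=200,
        ppi_attach=2,
        planted_module_size=25,
        n_gene_universe=600,
        cohort_sizes=(150, 150),
        exposure_probs=(0.3, 0.15),
    )


@pytest.fixture()
def toy_edges():
    """Tiny STRING-style edge table (integer scores on the 0-1000 scale)."""
    rows = [
        ("A", "B", 800, 0, 0),
        ("B", "C", 0, 750, 0),
        ("C", "A", 600, 500, 0),  # noisy-OR 0.8
        ("C", "D", 699, 0, 0),  # below threshold
        ("D", "E", 700, 0, 0),  # exactly at threshold
        ("E", "F", 0, 0, 900),
        ("X", "Y", 950, 0, 0),
    ]
    df = pd.DataFrame(rows, columns=["protein1", "protein2", "experiments", "databases", "fusion"])
    df["combined_score"] = df[["experiments", "databases", "fusion"]].max(axis=1)
    return df


@pytest.fixture()
def toy_gmt_text():
    return (
        "P1\tfirst\tG1\tG2\tG3\tG4\n"
        "P2\tsecond\tG3\tG4\tG5\n"
        "P3\tthird\tG6\tG7\tG8\tG9\tG10\n"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
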