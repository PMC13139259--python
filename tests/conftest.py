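import numpy as np
import pandas as pd
import pytest

from microgdi import OtuTable, SimulationSpec, simulate_otu_table, simulate_trait_table


@pytest.fixture
def tiny_table():
    """Three samples, four OTUs, hand-checkable counts."""
    counts = pd.DataFrame(
        [[30, 70, 0, 1], [10, 10, 10, 0], [0, 0, 5, 995]],
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        columns=["OTU_1", "OTU_2", "OTU_3", "OTU_W"],
    )
    meta = pd.DataFrame(
        {
            "line_id": ["l1", "l1", "l2"],
            "diet": ["control", "restricted", "control"],
            "replicate": [1, 1, 1],
        },
        index=counts.index,
    )
    tax = pd.DataFrame(
        {
            "genus": ["Leuconostoc", "Acetobacter", "Weissella", "Wolbachia"],
            "species": ["L pseudo", "A persici", "unknown", "W pipientis"],
        },
        index=pd.Index(counts.columns, name="otu_id"),
    )
    return OtuTable(counts, meta, tax)


@pytest.fixture(scope="session")
def sim_table():
    """A small simulated study shared across tests (20 lines, 300 OTUs)."""
    return simulate_otu_table(SimulationSpec(n_lines=20, n_otus=300, seed=42))


@pytest.fixture(scope="session")
def sim_traits():
    """Balanced 40-line trait table on the Gaussian scale."""
    return simulate_trait_table(SimulationSpec(n_lines=40, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
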