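import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from hybridbiome.simulate import SimConfig, simulate_populations
from hybridbiome.tableio import SampleTable

FOUR_TIP_NEWICK = "((A:1,B:1):1,(C:1,D:1):1):0;"


@pytest.fixture
def four_tip_tree():
    return TreeNode.read([FOUR_TIP_NEWICK])


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        {
            "h1": [5, 0, 3, 12000],
            "h2": [2, 2, 4, 11000],
            "m1": [0, 7, 1, 10500],
            "m2": [1, 9, 0, 10200],
        },
        index=["A", "B", "C", "D"],
    )
    taxonomy = {
        "A": "Bacteria;Actinobacteria;g__Dietzia",
        "B": "Bacteria;Firmicutes;g__Bacillus",
        "C": "Archaea;Euryarchaeota;g__Methanobrevibacter",
        "D": "Bacteria;Proteobacteria;g__Pseudomonas",
    }
    metadata = pd.DataFrame(
        {
            "species": ["hyb", "hyb", "mat", "mat"],
            "site": ["s1", "s1", "s1", "s1"],
            "role": ["hybrid", "hybrid", "maternal", "maternal"],
            "body_site": ["gut"] * 4,
        },
        index=pd.Index(["h1", "h2", "m1", "m2"], name="sample_id"),
    )
    return SampleTable(counts, taxonomy, metadata)


@pytest.fixture(scope="session")
def sim_dataset():
    """A small but realistic simulated study, shared across tests."""
    cfg = SimConfig(
        seed=11, n_individuals=15, n_shared=60, n_p1_only=30, n_p2_only=30,
        n_novel=30, read_depth=8000,
    )
    return simulate_populations(cfg)


@pytest.fixture(scope="session")
def sim_pops(sim_dataset):
    table, _, _ = sim_dataset
    md = table.metadata
    return {p: list(md.index[md["population"] == p])
            for p in sorted(md["population"].unique())}
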