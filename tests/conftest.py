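import numpy as np
import pytest

from rusitec.diversity import OtuTable, PhyloTree
from rusitec.synthetic import SimulationConfig


@pytest.fixture
def small_table() -> OtuTable:
    """3 samples x 4 OTUs with taxonomy over two genera."""
    counts = np.array([
        [10, 5, 0, 1],
        [0, 8, 4, 2],
        [3, 3, 3, 3],
    ])
    taxonomy = {
        "O1": ("Euryarchaeota", "Methanobrevibacter"),
        "O2": ("Euryarchaeota", "Methanobrevibacter"),
        "O3": ("Euryarchaeota", "Methanosphaera"),
        "O4": ("Crenarchaeota", "unclassified"),
    }
    return OtuTable(counts=counts, sample_ids=["S1", "S2", "S3"],
                    otu_ids=["O1", "O2", "O3", "O4"], taxonomy=taxonomy)


@pytest.fixture
def small_tree() -> PhyloTree:
    """Rooted 4-tip tree matching small_table's OTUs."""
    return PhyloTree.from_newick("((O1:0.5,O2:0.5):1.0,(O3:0.8,O4:1.2):0.7):0.0;")


@pytest.fixture
def tiny_config() -> SimulationConfig:
    """Down-scaled simulation: 2 runs, 200 OTUs, shallow reads."""
    return SimulationConfig(
        seed=42, n_runs=2, n_otus=200,
        read_depth_mean=5000.0, read_depth_sd=300.0, read_depth_min=4200,
        rarefaction_depth=4200,
    )
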