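import numpy as np
import pandas as pd
import pytest

from microgeostat import OtuTable, SimulationConfig, simulate_community, simulate_transect


@pytest.fixture
def small_table() -> OtuTable:
    counts = pd.DataFrame(
        [[1, 2], [3, 4]],
        index=["OTU_1", "OTU_2"], columns=["S1", "S2"],
    )
    tax = pd.Series(
        ["k__Archaea; p__Euryarchaeota; c__; o__; f__; g__a",
         "k__Bacteria; p__Proteobacteria; c__; o__; f__; g__b"],
        index=["OTU_1", "OTU_2"],
    )
    return OtuTable(counts, taxonomy=tax)


@pytest.fixture
def random_table() -> OtuTable:
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(20, 6))
    counts[0] += 1  # no all-zero taxon row needed, but keep table non-empty
    phyla = ["Euryarchaeota", "Thaumarchaeota", "Proteobacteria",
             "Bacteroidetes"]
    tax = {}
    for i in range(20):
        dom = "Archaea" if i < 8 else "Bacteria"
        tax[f"T{i:02d}"] = (f"k__{dom}; p__{phyla[i % 4]}; c__c{i % 3}; "
                            f"o__; f__; g__g{i}")
    return OtuTable(counts, taxonomy=pd.Series(tax),
                    taxon_ids=list(tax), sample_ids=[f"S{j}" for j in range(6)])


@pytest.fixture
def transect_metadata() -> pd.DataFrame:
    return simulate_transect(SimulationConfig(seed=7))


@pytest.fixture
def transect_community(transect_metadata) -> OtuTable:
    return simulate_community(transect_metadata, SimulationConfig(seed=7))


@pytest.fixture
def line_coords():
    """13 points on a 211 m one-dimensional transect."""
    return np.column_stack([np.linspace(0.0, 211.0, 13), np.zeros(13)])
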