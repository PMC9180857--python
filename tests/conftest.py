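import numpy as np
import pandas as pd
import pytest

from soilecotox import synthetic_data as sd
from soilecotox.community_diversity import OtuTable


@pytest.fixture
def design():
    """Paper-style 4 x 2 x 3 design with 3 replicates (72 units)."""
    return sd.build_design(3)


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


@pytest.fixture
def small_otu_table():
    """Hand-written 5-taxon, 3-sample table for exact arithmetic checks."""
    counts = pd.DataFrame(
        {
            "s1": [25, 75, 0, 0, 0],
            "s2": [10, 10, 20, 0, 60],
            "s3": [0, 0, 0, 100, 0],
        },
        index=pd.Index(["t1", "t2", "t3", "t4", "t5"], name="taxon_id"),
    )
    lineage = pd.DataFrame(
        {
            "phylum": ["P1", "P1", "P2", "P2", "P2"],
            "class": ["C1", "C1", "C2", "C2", "C3"],
            "genus": ["g1", "g2", "g3", "g4", "g5"],
        },
        index=counts.index,
    )
    return OtuTable(counts=counts, lineage=lineage, sample_groups={"s1": "C", "s2": "B", "s3": "Zn"})
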