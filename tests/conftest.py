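import numpy as np
import pytest

from propstab.tables import AbundanceTable, MetadataTable, SampleRecord
from propstab.synth import SyntheticConfig, generate_experiment


@pytest.fixture
def small_table() -> AbundanceTable:
    counts = np.array([
        [5, 0, 2],
        [3, 1, 0],
        [0, 4, 4],
    ])
    taxonomy = {
        "asv1": ("Bacteria", "p1", "c1", "o1", "famA", "g1", None),
        "asv2": ("Bacteria", "p1", "c1", "o1", "famA", "g2", None),
        "asv3": ("Bacteria", "p1", "c1", "o2", "famB", "g3", None),
    }
    return AbundanceTable(["asv1", "asv2", "asv3"], ["s1", "s2", "s3"],
                          counts, taxonomy)


@pytest.fixture
def tiny_metadata() -> MetadataTable:
    """Two lineages through two generations."""
    recs = [
        SampleRecord("g0a", "O1", 0, "O1.R1", None, "R1", 3.0, 40.0, 0.5),
        SampleRecord("g0b", "O1", 0, "O1.R2", None, "R2", 4.0, 38.0, 0.6),
        SampleRecord("g1a", "O1", 1, "O1.L1", "g0a", "L1", 2.2, 41.0, 0.5),
        SampleRecord("g1b", "O1", 1, "O1.L2", "g0b", "L2", 4.0, 39.0, 0.4),
        SampleRecord("g2a", "O1", 2, "O1.L1", "g1a", "L1", 2.9, 40.0, 0.5),
        SampleRecord("g2b", "O1", 2, "O1.L2", "g1b", "L2", 3.1, 42.0, 0.6),
    ]
    return MetadataTable(recs)


@pytest.fixture(scope="session")
def default_experiment():
    """Default-design synthetic experiment (10 origins, 180 samples)."""
    cfg = SyntheticConfig(seed=7, n_taxa_bacteria=80, n_taxa_fungi=30,
                          seq_depth_bacteria=2000, seq_depth_fungi=2000,
                          transfer_depth=2000)
    return cfg, generate_experiment(cfg)
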