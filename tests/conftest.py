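import numpy as np
import pytest

from chromostruct.model import ContigSet, MarkerRecord
from chromostruct.simulate import SimConfig, simulate_genome


@pytest.fixture(scope="session")
def small_genome():
    """Two-chromosome genome with sequence, satellites, TEs, and genes."""
    cfg = SimConfig(
        chrom_lengths=(2_000_000, 1_500_000),
        satellite_array_length=100_000,
        n_genes=40,
        seed=7,
        with_sequence=True,
    )
    return simulate_genome(cfg)


@pytest.fixture
def three_markers():
    return [
        MarkerRecord("m1", "LG1", 0.0, "ctg1", 1_000),
        MarkerRecord("m2", "LG1", 5.5, "ctg1", 50_000, strand="+"),
        MarkerRecord("m3", "LG2", 12.25, "ctg2", 2_500, strand="-"),
    ]


@pytest.fixture
def tiny_contigs():
    return ContigSet(sequences={"ctg1": "ACGT" * 250, "ctg2": "GGCC" * 500})
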