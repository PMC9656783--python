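import numpy as np
import pytest

from genesift.catalog import GeneCatalog, GeneEntry
from genesift import simulate


@pytest.fixture
def small_catalog() -> GeneCatalog:
    """Hand-built 6-gene catalog with known loci and one alias."""
    return GeneCatalog([
        GeneEntry("HNF4A", ("TCF14",), "chr20", 44_355_000),
        GeneEntry("TCF7L2", (), "chr10", 112_950_000),
        GeneEntry("HLA-DRB1", (), "chr6", 32_578_000),
        GeneEntry("TIMP1", (), "chrX", 47_582_000),
        GeneEntry("POMC", (), "chr2", 25_160_000),
        GeneEntry("NEAR1", (), "chrX", 47_900_000),   # 318 kb from TIMP1
    ])


@pytest.fixture
def gen_catalog() -> GeneCatalog:
    return simulate.generate_catalog(n_genes=60, n_chromosomes=5, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
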