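import numpy as np
import pytest

from admecov.core import GenomicPosition
from admecov.io import load_adme_panel, load_platform_matrix
from admecov.ld import HaplotypePanel


@pytest.fixture(scope="session")
def adme_panel():
    return load_adme_panel()


@pytest.fixture(scope="session")
def platform_matrix():
    return load_platform_matrix()


def make_panel(columns, chrom="1", start=1000, spacing=1000, ids=None, population=None):
    """HaplotypePanel from a list of allele columns, evenly spaced sites."""
    alleles = np.column_stack([np.asarray(c, dtype=np.int8) for c in columns])
    positions = [
        GenomicPosition(chrom, start + i * spacing) for i in range(len(columns))
    ]
    return HaplotypePanel(
        alleles=alleles,
        site_positions=positions,
        site_ids=ids,
        population=population,
    )


@pytest.fixture
def haplotype_factory():
    return make_panel
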