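import numpy as np
import pytest

from dipdesign.config import DesignConfig
from dipdesign.pipeline import design_library
from dipdesign.synthetic_fixtures import SimulationConfig, make_synthetic_plasmid

DOMAIN = "GATCTGGAAGCAAACCTGTTCGAA" * 4  # 96-nt in-frame toy domain


@pytest.fixture(scope="session")
def plasmid_300():
    """Seeded 300-codon synthetic target used across design tests."""
    return make_synthetic_plasmid(SimulationConfig(seed=1, gene_length_codons=300))


@pytest.fixture(scope="session")
def design_300(plasmid_300):
    """Complete library design for the shared 300-codon target."""
    return design_library(plasmid_300, DesignConfig(seed=1), gene_name="synth1")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
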