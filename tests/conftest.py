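import numpy as np
import pytest
from hypothesis import settings

from haplokit import collapse_haplotypes, variable_sites
from haplokit.datasets import (
    GROUPS,
    reference_hamming,
    reference_haplotype_set,
    synthetic_cytb_alignment,
)
from haplokit.seqio import build_population_map

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_hs():
    """The bundled 20-haplotype reference set (41-site strings)."""
    return reference_haplotype_set()


@pytest.fixture(scope="session")
def ref_hamming():
    return reference_hamming()


@pytest.fixture(scope="session")
def cytb_alignment():
    """Synthetic reconstruction of the 120 x 373 bp study alignment."""
    return synthetic_cytb_alignment()


@pytest.fixture(scope="session")
def cytb_pm(cytb_alignment):
    return build_population_map(cytb_alignment, groups=GROUPS)


@pytest.fixture(scope="session")
def cytb_hs(cytb_alignment):
    return collapse_haplotypes(cytb_alignment)


@pytest.fixture(scope="session")
def cytb_vst(cytb_hs):
    return variable_sites(cytb_hs)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
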