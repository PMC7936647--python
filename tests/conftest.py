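from pathlib import Path

import numpy as np
import pytest

from mutspect import GenomeAccessor, synthetic_signatures
from mutspect.synthetic_data import generate_reference

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def syn_sigs():
    return synthetic_signatures()


@pytest.fixture(scope="session")
def ref100k():
    """One shared synthetic reference for tests that only need a genome."""
    return generate_reference(genome_length=100_000, seed=11)


@pytest.fixture(scope="session")
def genome100k(ref100k):
    return GenomeAccessor({ref100k.chrom: ref100k.sequence})


@pytest.fixture
def rng():
    return np.random.default_rng(2021)


@pytest.fixture(scope="session")
def toy_vcf_path():
    return DATA / "toy20.vcf"


@pytest.fixture(scope="session")
def blacklist_bed_path():
    return DATA / "blacklist.bed"
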