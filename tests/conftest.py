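import numpy as np
import pytest

from mutsig.io import GenomeSequence, MutationRecord, MutationSet
from mutsig.simulate import SyntheticConfig, simulate_cohort


@pytest.fixture
def tiny_genome():
    return GenomeSequence({
        "chrI": "ACCGATTACCGGATCCGAATGCGT",
        "chrII": "TTTTACGTACGTACGTACGTAAAA",
    })


@pytest.fixture
def sbs(tiny_genome):
    def make(chrom, pos, ref, alt, sample="s1", vaf=0.95):
        assert tiny_genome[chrom][pos - 1] == ref
        return MutationRecord(sample, chrom, pos, ref, alt, vaf)

    return make


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=23, n_chromosomes=2, chrom_length=150_000,
                           n_isolates=8, sbs_per_isolate=50,
                           subtelomere_bp=30_000)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """One modest synthetic cohort shared by read-only tests."""
    return simulate_cohort(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_set(records):
    return MutationSet(list(records))
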