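import numpy as np
import pytest

from mutasym import (
    CatalogSimParams,
    MutationRecord,
    SyntheticGenomeSpec,
    make_reference,
    simulate_catalog,
)


def make_record(chrom="chr1", pos=100, ref="A", alt="G", sample="S0",
                depth=40, af=0.5):
    return MutationRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                          sample_id=sample, depth=depth, alt_fraction=af)


@pytest.fixture(scope="session")
def small_reference():
    """Two 60-kb chromosomes, 8 transcripts, 3 origins each."""
    spec = SyntheticGenomeSpec(
        seed=11, n_chromosomes=2, chrom_length=60_000, n_transcripts=8,
        transcript_length_range=(1500, 2500), intergenic_min=500,
        origins_per_chromosome=3,
    )
    return spec, make_reference(spec)


@pytest.fixture(scope="session")
def default_reference():
    """The generator's default-sized genome (2 x 200 kb, 40 transcripts)."""
    spec = SyntheticGenomeSpec(seed=2)
    return spec, make_reference(spec)


@pytest.fixture(scope="session")
def small_catalogs(small_reference):
    _, (genome, transcripts, origins) = small_reference
    params = CatalogSimParams(seed=5, n_samples=4,
                              mutations_per_genome_mean=150)
    return simulate_catalog(genome, transcripts, origins, params,
                            genotype="wt")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
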