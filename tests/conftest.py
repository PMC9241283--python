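import pysam
import pytest

import genochain as g

#: Fixture conditions: a 300-kbp chromosome with 1,000 150-bp reads at a 1%
#: mismatch / 0.1% indel rate, 2% soft-clips, 2% unmapped reads; 50-kbp bins
#: so reads regularly straddle bin boundaries (FLANK=1).
SMALL = g.SimulationParams(
    seed=11,
    chromosomes=(("chrA", 300_000),),
    n_reads=1_000,
    read_length=150,
    mismatch_rate=0.01,
    insertion_rate=0.001,
    deletion_rate=0.001,
    softclip_rate=0.02,
    unmapped_fraction=0.02,
    n_variants=1_000,
    het_fraction=0.5,
)

SMALL_CONFIG = g.ChainConfig(
    chromosomes=SMALL.chromosomes,
    bin_length=50_000,
    declared_read_length=300,
    reference_id="synthetic-small",
)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Synthetic reference + SAM + VCF for the small study conditions."""
    d = tmp_path_factory.mktemp("fixtures")
    g.make_reference(SMALL, d / "ref.fa")
    g.simulate_reads(d / "ref.fa", SMALL, d / "reads.sam")
    g.simulate_vcf(d / "ref.fa", SMALL, d / "variants.vcf")
    return d


@pytest.fixture(scope="session")
def reference(fixture_dir):
    with pysam.FastaFile(str(fixture_dir / "ref.fa")) as fa:
        yield fa


@pytest.fixture(scope="session")
def populated_samchain(tmp_path_factory, fixture_dir):
    """A SAMchain holding the small fixture (read-only across tests)."""
    chain = g.Chain.create(tmp_path_factory.mktemp("chain") / "samchain",
                           name="SAMchain")
    sc = g.build_chain(chain, SMALL_CONFIG)
    report = g.insert_data(sc, fixture_dir / "reads.sam",
                           fixture_dir / "ref.fa")
    return sc, report


@pytest.fixture()
def fresh_chain(tmp_path):
    return g.Chain.create(tmp_path / "chain")
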