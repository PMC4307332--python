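import pytest

from splicevar import ScenarioSpec, generate_scenario
from splicevar.annotation_io import GenomeRef, GenomicInterval, TranscriptModel


@pytest.fixture(scope="session")
def bundle_factory(tmp_path_factory):
    """Generate (and cache) preset bundles keyed by (name, seed, strand)."""
    cache = {}

    def make(name, seed=1, strand="+"):
        key = (name, seed, strand)
        if key not in cache:
            out = tmp_path_factory.mktemp("bundle")
            cache[key] = generate_scenario(
                ScenarioSpec(name=name, seed=seed, strand=strand), out
            )
        return cache[key]

    return make


@pytest.fixture
def toy_genome():
    #            0         1         2         3
    #            0123456789012345678901234567890123456789
    return GenomeRef({"chr1": "ATGAAACCCGGGTTTACGTACGTACGGTAAGCCCTTTAG" + "A" * 61})


@pytest.fixture
def two_exon_plus():
    return TranscriptModel(
        transcript_id="t1",
        gene_id="g1",
        exons=[
            GenomicInterval("chr1", 0, 10),
            GenomicInterval("chr1", 20, 30),
        ],
    )
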