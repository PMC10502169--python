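import pytest
from hypothesis import settings

from grnakit.genome_io import Contig, Feature, Genome, build_store
from grnakit.simkit import SimSpec, random_annotation, random_genome

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_genome():
    """400 bp single-contig genome with a deterministic repeating sequence."""
    seq = ("ACGTTGCAGGATCCTAGGCA" * 20)[:400]
    return Genome(name="toy", contigs=[Contig(id="c1", seq=seq)])


@pytest.fixture(scope="session")
def toy_store():
    """Two genes on c1: LOCA + strand [100,200), LOCB - strand [250,350)."""
    feats = []
    for locus, start, end, strand in (("LOCA", 100, 200, "+"), ("LOCB", 250, 350, "-")):
        feats.append(Feature(f"gene_{locus}", locus, "c1", start, end, strand, "gene"))
        feats.append(
            Feature(f"cds_{locus}", locus, "c1", start, end, strand, "CDS",
                    parent_id=f"gene_{locus}")
        )
    return build_store(feats)


@pytest.fixture(scope="session")
def sim20k():
    """20 kb / 10-gene synthetic genome with its annotation store."""
    spec = SimSpec(contig_len=20_000, n_genes=10, seed=42)
    genome = random_genome(spec)
    store = build_store(random_annotation(genome, spec))
    return genome, store
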