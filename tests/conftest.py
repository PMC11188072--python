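import numpy as np
import pytest

from ismorf.io_formats import AnnotatedGenome, FeatureRecord, GenomeSequence


def make_genome(sequence: str, genes: list[tuple[int, int, str]],
                genome_id: str = "g1", contig_id: str = "c1",
                circular: bool = False) -> AnnotatedGenome:
    """Toy single-contig genome with gene features at the given spans."""
    features = [
        FeatureRecord(contig_id=contig_id, start=s, end=e, strand=strand,
                      feature_id=f"{genome_id}_gene{i}", feature_type="gene",
                      product=f"protein {i}")
        for i, (s, e, strand) in enumerate(genes)
    ]
    return AnnotatedGenome(
        genome_id=genome_id,
        contigs=[GenomeSequence(contig_id=contig_id, sequence=sequence,
                                genome_id=genome_id, circular=circular)],
        features=features,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))
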