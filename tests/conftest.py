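import numpy as np
import pytest

from togaregulon.genome_model import GeneRecord, GenomeAnnotation, UpstreamRegion


def make_region(seq: str, operon_id: str = "op1", genome_id: str = "g1") -> UpstreamRegion:
    return UpstreamRegion(
        operon_id=operon_id,
        genome_id=genome_id,
        contig_id="c1",
        sequence=seq,
        interval=(0, len(seq)),
        strand="+",
    )


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


@pytest.fixture
def toy_genome() -> GenomeAnnotation:
    """1 kb single-contig genome with three genes: A(+), B(+), C(-).

    1-based inclusive coordinates: A 301-450, B 500-650, C 701-900;
    gap A->B is 49 nt, so A and B chain into one operon at max_gap=100.
    """
    rng = np.random.default_rng(99)
    contig = random_dna(rng, 1000)
    genes = [
        GeneRecord("gA", "tg", "c1", 300, 450, "+", name="gA"),
        GeneRecord("gB", "tg", "c1", 499, 650, "+", name="gB"),
        GeneRecord("gC", "tg", "c1", 700, 900, "-", name="gC"),
    ]
    return GenomeAnnotation("tg", {"c1": contig}, genes)
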