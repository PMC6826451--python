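import numpy as np
import pytest

from igscluster.annotation_io import GeneRecord, GenomeAnnotation, TranscriptionUnit
from igscluster.synthetic_fixtures import FixtureSpec, simulate_genome


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_gene_annotation():
    """Circular 1000-bp replicon with two forward genes [0,300) and [500,800)."""
    rng = np.random.default_rng(7)
    seq = random_dna(rng, 1000)
    seq = seq[:0] + "ATG" + seq[3:500] + "ATG" + seq[503:]
    genes = [GeneRecord("gA", "+", 0, 300), GeneRecord("gB", "+", 500, 800)]
    return GenomeAnnotation("toy", seq, "circular", genes)


@pytest.fixture
def singleton_tus(two_gene_annotation):
    return [TranscriptionUnit(g.gene_id, (g.gene_id,), g.gene_id)
            for g in two_gene_annotation.genes]


@pytest.fixture(scope="session")
def simulated():
    """One deterministic synthetic genome shared by read-only tests."""
    spec = FixtureSpec(n_genes=60, rng_seed=3)
    annotation, tus, truth = simulate_genome(spec)
    return spec, annotation, tus, truth
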