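import numpy as np
import pytest

from granulekit.annotations import AnnotationSet, Feature, FeatureIndex, Operon
from granulekit.readproc import GenomeIndex
from granulekit.synthdata import SimConfig, make_genome


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def genome_annots(sim_config):
    return make_genome(sim_config)


@pytest.fixture(scope="session")
def genome(genome_annots):
    return genome_annots[0]


@pytest.fixture(scope="session")
def annots(genome_annots):
    return genome_annots[1]


@pytest.fixture(scope="session")
def findex(annots):
    return FeatureIndex(annots)


@pytest.fixture(scope="session")
def gindex(genome):
    return GenomeIndex(genome)


@pytest.fixture
def toy_annots():
    """Hand-built annotation set used for rule-level unit tests.

    chrT (10 kb): a plus-strand piRNA locus, a plus-strand coding gene with an
    antisense rRNA inside it, two fully overlapping coding genes, a tRNA, and
    a minus-strand gene.
    """
    features = [
        Feature("p1", "chrT", 1000, 1021, "+", "piRNA_locus"),
        Feature("pm", "chrT", 1200, 1221, "-", "piRNA_locus"),
        Feature("gA", "chrT", 2000, 2500, "+", "protein_coding",
                exons=[(2000, 2500)], utr5_start=2000),
        Feature("rr", "chrT", 2050, 2200, "+", "rRNA"),
        Feature("gB", "chrT", 3000, 3500, "+", "protein_coding",
                exons=[(3000, 3500)], utr5_start=3000),
        Feature("gC", "chrT", 3000, 3500, "+", "protein_coding",
                exons=[(3000, 3500)], utr5_start=3000),
        Feature("tr", "chrT", 4000, 4080, "+", "tRNA"),
        Feature("gM", "chrT", 5000, 5600, "-", "protein_coding",
                exons=[(5000, 5600)], utr5_start=5600),
    ]
    return AnnotationSet({"chrT": 10_000}, features)


@pytest.fixture
def toy_index(toy_annots):
    return FeatureIndex(toy_annots)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
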