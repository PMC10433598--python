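import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from curagap.gene_model import build_gene_model
from curagap.synth import CorpusSpec, synth_corpus, synth_gene_model

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def two_exon_model():
    """The minimal worked example: exons (1001-1100), (1201-1300), CDS from c.1."""
    return build_gene_model([(1001, 1100), (1201, 1300)])


@pytest.fixture
def seq_model():
    """Two-exon model with a fixed sequence (for shifting / ref checks).

    Exon 1 = g.1..30 (c.1..30), intron = g.31..90, exon 2 = g.91..120.
    """
    rng = np.random.default_rng(42)
    seq = list(rng.choice(list("ACGT"), 120))
    # a homopolymer run A T T T G at g.10..14 for the 3'-shift example
    seq[9:14] = list("ATTTG")
    # TGCCC at intron positions g.70..74, flanked by non-repeating bases
    seq[68:76] = list("GTGCCCAA")
    return build_gene_model([(1, 30), (91, 120)], sequence="".join(seq))


@pytest.fixture(scope="session")
def synth_model():
    return synth_gene_model(1)


@pytest.fixture(scope="session")
def default_corpus(synth_model):
    """One study-shaped synthetic corpus (210 mentions, 12% aliases)."""
    mentions, truth = synth_corpus(synth_model, CorpusSpec(seed=1))
    return mentions, truth
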