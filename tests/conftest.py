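import pytest

from genesetnet.corpus_io import Corpus, GeneSet, InteractionNetwork
from genesetnet.synthetic import generate, reference_config


def make_set(set_id, genes, pag_type="G", **kw):
    return GeneSet(id=set_id, name=set_id, pag_type=pag_type,
                   members=frozenset(genes), **kw)


def make_network(edges):
    """edges: iterable of (a, b) or (a, b, confidence)."""
    net = InteractionNetwork()
    for e in edges:
        net.add_edge(*e)
    return net


@pytest.fixture
def k4_network():
    genes = ["A", "B", "C", "D"]
    return make_network(
        (a, b, 1.0) for i, a in enumerate(genes) for b in genes[i + 1:]
    )


@pytest.fixture(scope="session")
def ref_data():
    """Reference synthetic dataset shared across the suite (seed 42)."""
    return generate(reference_config(42))


@pytest.fixture
def toy_corpus():
    return Corpus(sets=[
        make_set("S1", ["A", "B", "C"], "P"),
        make_set("S2", ["B", "C", "D"], "A"),
        make_set("S3", ["E"], "G"),
        make_set("S4", ["A", "D", "E", "F"], "G"),
    ])
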