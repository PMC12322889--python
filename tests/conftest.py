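import pytest

from nmdsplice import events, orf
from nmdsplice.synthetic import make_toy_gene


def prepared_gene(name: str, strand: str = "+"):
    """Fixture gene with NMDT flags annotated, plus its ground truth."""
    gene, expected = make_toy_gene(name, strand)
    orf.annotate_gene(gene)
    return gene, expected


def single_cluster(gene):
    """The one event cluster of a fixture gene."""
    evs, _ = events.find_events(gene)
    clusters = events.cluster_events(evs, gene.gene_id)
    assert len(clusters) == 1
    return clusters[0]


@pytest.fixture(scope="session")
def pe_cluster():
    gene, expected = prepared_gene("PE")
    return gene, single_cluster(gene), expected
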