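import networkx as nx
import pytest

from netindic.graph_io import DiseaseCatalog, DiseaseEntry
from netindic.propagation import Subnetwork


@pytest.fixture
def single_edge():
    return nx.Graph([("A", "B")])


@pytest.fixture
def path4():
    return nx.path_graph(["a", "b", "c", "d"])


@pytest.fixture
def star6():
    """Hub 'h' with five leaves l1..l5."""
    return nx.star_graph(["h", "l1", "l2", "l3", "l4", "l5"])


def make_entry(disease_id, seeds, mesh=None, scores=None, name=None):
    scores = scores or {g: 0.5 for g in seeds}
    return DiseaseEntry(
        disease_id=disease_id,
        name=name or f"disease {disease_id}",
        mesh_id=mesh or f"M{disease_id}",
        seed_genes=frozenset(seeds),
        gene_scores=scores,
    )


def make_catalog(*entries):
    return DiseaseCatalog(entries={e.disease_id: e for e in entries})


def subnet(nodes, origins=(), construction="disease"):
    return Subnetwork(frozenset(nodes), frozenset(origins), construction)
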