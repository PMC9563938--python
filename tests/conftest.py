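import numpy as np
import pytest

from semhub.corpus import TokenizedDoc
from semhub.kgraph import KnowledgeGraph, Node


def make_graph(nodes, edges):
    """Build a KnowledgeGraph from (id, ntype) pairs and (h, p, t, w) tuples."""
    g = KnowledgeGraph()
    for nid, ntype in nodes:
        g.add_node(Node(id=nid, name=nid.lower(), ntype=ntype))
    for h, p, t, w in edges:
        g.add_edge(h, p, t, w)
    return g


def random_typed_graph(seed, max_nodes=15, max_edges=40):
    """Small random typed graph for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_nodes + 1))
    ntypes = ["DSYN", "AAPP", "GNGM", "PHSU"]
    preds = ["CAUSES", "AFFECTS", "TREATS"]
    nodes = [(f"N{i:02d}", ntypes[int(rng.integers(len(ntypes)))])
             for i in range(n)]
    g = make_graph(nodes, [])
    m = int(rng.integers(1, max_edges + 1))
    for _ in range(m):
        h, t = rng.choice(n, size=2, replace=False)
        g.add_edge(f"N{h:02d}", preds[int(rng.integers(len(preds)))],
                   f"N{t:02d}", float(rng.integers(1, 6)))
    return g


@pytest.fixture
def toy_docs():
    """Three tiny documents with a known term layout."""
    return [TokenizedDoc("d1", ["a", "b"]),
            TokenizedDoc("d2", ["a", "c"]),
            TokenizedDoc("d3", ["a", "b", "c"])]


@pytest.fixture
def six_edge_graph():
    return make_graph(
        [("C1", "PHSU"), ("C2", "GNGM"), ("C3", "DSYN"), ("C4", "DSYN"),
         ("C5", "AAPP")],
        [("C1", "INHIBITS", "C2", 12.0),
         ("C1", "TREATS", "C3", 3.0),
         ("C2", "CAUSES", "C3", 2.0),
         ("C2", "CAUSES", "C4", 1.0),
         ("C5", "AFFECTS", "C3", 4.0),
         ("C5", "AFFECTS", "C4", 5.0)])
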