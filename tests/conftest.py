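import networkx as nx
import numpy as np
import pandas as pd
import pytest

from trn_adapt import synthetic as syn
from trn_adapt.network import RegulonTable


def regulon_from_edges(edges) -> RegulonTable:
    """Build a RegulonTable from (regulator, target[, effect]) tuples."""
    rows = []
    for e in edges:
        reg, tgt = e[0], e[1]
        effect = e[2] if len(e) > 2 else "activation"
        rows.append({"regulator": reg, "target": tgt, "effect": effect})
    return RegulonTable(pd.DataFrame(rows))


def digraph_from_adjacency(adj: np.ndarray) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(adj.shape[0]))
    g.add_edges_from(zip(*np.nonzero(adj)))
    return g


@pytest.fixture(scope="session")
def archetype_study():
    """One simulated study containing all four knockout adaptation archetypes."""
    return syn.simulate_study(syn.archetype_spec(seed=11))


@pytest.fixture()
def chain_graph():
    g = nx.DiGraph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g
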