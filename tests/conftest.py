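"""Shared fixtures: synthetic bundles and small hand-built networks."""

from __future__ import annotations

import pandas as pd
import pytest

from chdprio import network as net
from chdprio import simulate as sim
from chdprio.genesets import GeneSet


@pytest.fixture(scope="session")
def bundle() -> sim.SyntheticBundle:
    """Default planted-module bundle, shared read-only across tests."""
    return sim.generate(sim.SyntheticConfig(seed=1))


def make_edge_store(edges: list[tuple[str, str, float]],
                    threshold: float = 0.0) -> net.EdgeStore:
    """EdgeStore from (a, b, combined_score) triples in the 0-1 dialect."""
    df = pd.DataFrame(edges, columns=["protein1", "protein2", "combined_score"])
    return net.edges_from_frame(df, threshold)


def make_network(edges: list[tuple[str, str]],
                 categories: dict[str, str] | None = None,
                 extra_nodes: list[str] | None = None,
                 hide_disconnected: bool = True):
    """Toy induced network from unscored edge pairs."""
    store = make_edge_store([(a, b, 0.9) for a, b in edges])
    nodes = {n for e in edges for n in e} | set(extra_nodes or [])
    return net.induce_network(GeneSet("toy", frozenset(nodes)),
                              categories or {}, store,
                              hide_disconnected=hide_disconnected)
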