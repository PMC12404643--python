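"""Confidence-scored PPI edge tables and induced interaction networks.

Edge tables follow the STRING ``protein.links``-style flat-file dialect:
whitespace- or tab-separated with a header, columns ``protein1``,
``protein2`` and ``combined_score`` (plus optional per-channel score
columns).  Combined scores may be printed either as integers on a
0-1000 scale or as reals in [0,1]; the integer dialect is divided by
1000 on load.  The confidence threshold is inclusive (score >= 0.7
passes at the default "high confidence" cutoff), edges are undirected
with symmetric duplicates collapsed, and self-loops are dropped.

Nodes are gene symbols, mapped 1:1 to proteins; no isoform expansion.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from chdprio.genesets import GeneSet

logger = logging.getLogger(__name__)

HIGH_CONFIDENCE = 0.7  # STRING's "high confidence" minimum interaction score

NEIGHBOR = "neighbor"  # category for nodes pulled in only as first neighbors


class EdgeStore:
    """Canonicalized, threshold-filtered undirected scored edges."""

    def __init__(self, frame: pd.DataFrame, threshold: float):
        self.frame = frame  # columns protein_a < protein_b, combined_score, channels
        self.threshold = threshold
        self._adjacency: dict[str, set[str]] | None = None

    @property
    def proteins(self) -> frozenset[str]:
        if len(self.frame) == 0:
            return frozenset()
        return frozenset(self.frame["protein_a"]) | frozenset(self.frame["protein_b"])

    def adjacency(self) -> dict[str, set[str]]:
        if self._adjacency is None:
            adj: dict[str, set[str]] = {}
            for a, b in zip(self.frame["protein_a"], self.frame["protein_b"]):
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
            self._adjacency = adj
        return self._adjacency

    def __len__(self) -> int:
        return len(self.frame)


def _canonicalize(df: pd.DataFrame, threshold: float, source: str) -> EdgeStore:
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    bad = scores.index[scores.isna()]
    if len(bad):
        raise ValueError(f"{source}: malformed combined_score at row {bad[0] + 1}")
    channel_cols = [c for c in df.columns
                    if c not in ("protein1", "protein2", "combined_score")]
    # dialect detection: any score > 1 means the 0-1000 integer scale
    if (scores > 1).any():
        if (scores > 1000).any() or (scores < 0).any():
            raise ValueError(f"{source}: combined_score outside both the 0-1 "
                             "and 0-1000 dialects")
        scores = scores / 1000.0
        for c in channel_cols:
            df[c] = pd.to_numeric(df[c], errors="coerce") / 1000.0
    elif (scores < 0).any():
        raise ValueError(f"{source}: negative combined_score")

    a = df["protein1"].astype(str).str.strip()
    b = df["protein2"].astype(str).str.strip()
    self_loops = (a == b)
    if self_loops.any():
        logger.warning("%s: dropped %d self-loop(s), e.g. %s",
                       source, int(self_loops.sum()), a[self_loops].iloc[0])
    keep = ~self_loops
    lo = np.minimum(a[keep].to_numpy(), b[keep].to_numpy())
    hi = np.maximum(a[keep].to_numpy(), b[keep].to_numpy())
    out = pd.DataFrame({"protein_a": lo, "protein_b": hi,
                        "combined_score": scores[keep].to_numpy()})
    for c in channel_cols:
        out[c] = df.loc[keep, c].to_numpy()
    # symmetric duplicates collapse to the maximum reported confidence
    out = (out.sort_values("combined_score", ascending=False)
              .drop_duplicates(subset=["protein_a", "protein_b"], keep="first"))
    out = out[out["combined_score"] >= threshold].reset_index(drop=True)
    out = out.sort_values(["protein_a", "protein_b"]).reset_index(drop=True)
    return EdgeStore(out, threshold)


def load_edge_table(path: str | Path, score_threshold: float = HIGH_CONFIDENCE) -> EdgeStore:
    """Read a STRING-style scored edge file and apply the confidence cutoff."""
    df = pd.read_csv(path, sep=r"\s+")
    required = {"protein1", "protein2", "combined_score"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: edge table needs columns {sorted(required)}")
    return _canonicalize(df, score_threshold, str(path))


def edges_from_frame(df: pd.DataFrame, score_threshold: float = HIGH_CONFIDENCE) -> EdgeStore:
    """Build an EdgeStore from an in-memory frame in the same dialect."""
    return _canonicalize(df.copy(), score_threshold, "<frame>")


def induce_network(query: GeneSet, categories: Mapping[str, str],
                   edges: EdgeStore, hide_disconnected: bool = True) -> nx.Graph:
    """Network over the query genes: induced edges at the store's threshold.

    Edges = stored edges with both endpoints in the query.  With
    ``hide_disconnected`` (the published setting), zero-degree nodes —
    including query genes absent from the edge table's protein space —
    are removed; otherwise every query gene appears as a node.  Categories from the assignment are attached as the node
    attribute ``category`` (genes absent from the assignment become
    first-shell ``neighbor`` nodes).
    """
    g = nx.Graph(threshold=edges.threshold, hide_disconnected=hide_disconnected)
    g.add_nodes_from(query.members)
    sub = edges.frame[
        edges.frame["protein_a"].isin(query.members)
        & edges.frame["protein_b"].isin(query.members)
    ]
    for row in sub.itertuples(index=False):
        g.add_edge(row.protein_a, row.protein_b,
                   combined_score=float(row.combined_score))
    if hide_disconnected:
        isolated = [n for n in g.nodes if g.degree(n) == 0]
        g.remove_nodes_from(isolated)
    nx.set_node_attributes(
        g, {n: categories.get(n, NEIGHBOR) for n in g.nodes}, "category")
    if g.number_of_nodes() == 0:
        logger.warning("induced network is empty (query disjoint from edge table)")
    return g


def ppi_enrichment_p(network: nx.Graph, background: EdgeStore,
                     n_perm: int = 999, seed: int = 0,
                     degree_binned: bool = False, n_bins: int = 10) -> dict[str, float]:
    """Monte-Carlo PPI edge-enrichment p-value.

    Tests whether the network carries more induced edges than random
    protein sets of the same size drawn from the background protein
    universe:  p = (1 + #{null >= observed}) / (n_perm + 1), bounded
    below by 1/(n_perm+1).  The default null is degree-naive uniform
    sampling; ``degree_binned`` stratifies draws by background-degree
    decile as a sensitivity mode.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    proteins = sorted(background.proteins)
    n_nodes = network.number_of_nodes()
    if n_nodes > len(proteins):
        raise ValueError(
            f"background ({len(proteins)} proteins) smaller than the network "
            f"({n_nodes} nodes)")
    observed = network.number_of_edges()
    adj = background.adjacency()
    rng = np.random.default_rng(seed)

    if degree_binned:
        degrees = np.array([len(adj.get(p, ())) for p in proteins])
        quantiles = np.quantile(degrees, np.linspace(0, 1, n_bins + 1)[1:-1])
        bins = np.searchsorted(quantiles, degrees, side="right")
        node_bins = Counter(
            int(bins[proteins.index(n)]) for n in network.nodes if n in set(proteins))
        pools = {b: [p for p, pb in zip(proteins, bins) if pb == b]
                 for b in set(bins)}

    null_counts = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        if degree_binned:
            sample: list[str] = []
            for b, cnt in node_bins.items():
                pool = pools[b]
                sample.extend(rng.choice(pool, size=min(cnt, len(pool)),
                                         replace=False))
            chosen = set(sample)
        else:
            chosen = set(rng.choice(proteins, size=n_nodes, replace=False))
        count = 0
        for p in chosen:
            count += len(adj.get(p, set()) & chosen)
        null_counts[i] = count // 2
    n_ge = int((null_counts >= observed).sum())
    return {
        "observed_edges": float(observed),
        "null_mean": float(null_counts.mean()),
        "p_perm": (1 + n_ge) / (n_perm + 1),
    }


def degree_distribution(network: nx.Graph) -> dict[int, int]:
    """Histogram of node degrees; counts sum to the node count."""
    return dict(Counter(d for _, d in network.degree()))


def write_network(network: nx.Graph, edge_path: str | Path,
                  node_path: str | Path) -> None:
    """Export as a TSV edge list plus a TSV node-attribute table."""
    edges = pd.DataFrame(
        [(a, b, d.get("combined_score", float("nan")))
         for a, b, d in network.edges(data=True)],
        columns=["protein_a", "protein_b", "combined_score"],
    ).sort_values(["protein_a", "protein_b"])
    edges.to_csv(edge_path, sep="\t", index=False)
    nodes = pd.DataFrame(
        [(n, d.get("category", NEIGHBOR), network.degree(n))
         for n, d in network.nodes(data=True)],
        columns=["gene", "category", "degree"],
    ).sort_values("gene")
    nodes.to_csv(node_path, sep="\t", index=False)
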