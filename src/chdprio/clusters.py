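"""Functional-cluster scoring and first-neighbor subnetwork extraction.

Clusters are precomputed functionally coherent gene groups (e.g.,
STRING local network clusters); no de novo graph clustering is done
here.  Scoring restricts each cluster to genes present as network
nodes and ranks clusters by their richness in novel candidates —
genes in the candidate list but absent from the known disease-gene
list — percentage first, count second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from chdprio.genesets import BOTH, CANDIDATE_ONLY, KNOWN_ONLY, GeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterAnnotation:
    cluster_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id} has no members")


@dataclass(frozen=True)
class ClusterScore:
    cluster_id: str
    name: str
    n_in_network: int
    n_novel: int       # candidate_only members
    n_known: int       # known_only or both members
    frac_novel: float  # n_novel / n_in_network


def read_cluster_table(path: str | Path) -> list[ClusterAnnotation]:
    """TSV with columns cluster_id, name, members (comma-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cluster_id", "name", "members"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: cluster table needs columns {sorted(required)}")
    out = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.cluster_id in seen:
            raise ValueError(f"{path}: duplicate cluster_id {row.cluster_id!r}")
        seen.add(row.cluster_id)
        members = frozenset(m.strip() for m in str(row.members).split(",") if m.strip())
        out.append(ClusterAnnotation(str(row.cluster_id), str(row.name), members))
    return out


def write_cluster_scores(scores: list[ClusterScore], path: str | Path) -> None:
    pd.DataFrame([s.__dict__ for s in scores]).to_csv(path, sep="\t", index=False)


def score_clusters(clusters: list[ClusterAnnotation],
                   network: nx.Graph) -> list[ClusterScore]:
    """Rank clusters by novel-candidate richness.

    Primary key: fraction of in-network members that are novel
    candidates (candidate_only); secondary: the novel count; ties
    broken by cluster_id so the ordering is total and independent of
    input order.  Clusters with no member in the network are dropped
    with a warning.  The count-first alternative ordering is obtainable
    by re-sorting the returned scores, so both views stay auditable.
    """
    if not clusters:
        raise ValueError("score_clusters requires at least one cluster")
    categories = nx.get_node_attributes(network, "category")
    scores: list[ClusterScore] = []
    for cl in clusters:
        in_net = [m for m in cl.members if m in network]
        if not in_net:
            logger.warning("cluster %s has no members in the network; dropped",
                           cl.cluster_id)
            continue
        n_novel = sum(1 for m in in_net if categories.get(m) == CANDIDATE_ONLY)
        n_known = sum(1 for m in in_net if categories.get(m) in (KNOWN_ONLY, BOTH))
        scores.append(ClusterScore(
            cluster_id=cl.cluster_id, name=cl.name,
            n_in_network=len(in_net), n_novel=n_novel, n_known=n_known,
            frac_novel=n_novel / len(in_net),
        ))
    scores.sort(key=lambda s: (-s.frac_novel, -s.n_novel, s.cluster_id))
    return scores


def extract_subnetwork(network: nx.Graph, seeds: GeneSet) -> nx.Graph:
    """Induced subgraph on the seeds plus their direct neighbors.

    Reproduces the manual procedure of collecting every protein sharing
    a direct connection with any seed and rebuilding the network from
    that gene list alone: the result is the induced subgraph, so
    neighbor-neighbor edges are retained.  Seeds absent from the
    network are dropped with a warning; if none remain it is an error.
    """
    present = [s for s in seeds if s in network]
    missing = sorted(set(seeds) - set(present))
    if missing:
        logger.warning("%d seed(s) not in the network: %s",
                       len(missing), ", ".join(missing))
    if not present:
        raise ValueError("no seed gene is present in the network")
    nodes = set(present)
    for s in present:
        nodes |= set(network.neighbors(s))
    sub = network.subgraph(nodes).copy()
    sub.graph.update(network.graph)
    sub.graph["seeds"] = sorted(present)
    return sub
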