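"""Cluster scoring by novel-candidate richness and subnetwork extraction."""

import pytest

from chdprio.clusters import (ClusterAnnotation, extract_subnetwork,
                              read_cluster_table, score_clusters)
from chdprio.genesets import BOTH, CANDIDATE_ONLY, KNOWN_ONLY, GeneSet
from tests.conftest import make_network


def cluster(cid, members, name=None):
    return ClusterAnnotation(cid, name or cid, frozenset(members))


@pytest.fixture()
def categorized_network():
    cats = {"a1": CANDIDATE_ONLY, "a2": CANDIDATE_ONLY, "a3": CANDIDATE_ONLY,
            "a4": CANDIDATE_ONLY, "k1": KNOWN_ONLY, "k2": KNOWN_ONLY,
            "b1": BOTH}
    edges = [("a1", "a2"), ("a2", "a3"), ("a3", "a4"), ("a4", "k1"),
             ("k1", "k2"), ("k2", "b1"), ("b1", "a1")]
    return make_network(edges, categories=cats)


class TestScoreClusters:
    def test_fraction_ranks_first(self, categorized_network):
        clusters = [cluster("Q", {"k1", "k2", "a4"}),
                    cluster("P", {"a1", "a2", "a3"})]
        scores = score_clusters(clusters, categorized_network)
        assert [s.cluster_id for s in scores] == ["P", "Q"]
        assert scores[0].frac_novel == pytest.approx(1.0)
        assert scores[1].frac_novel == pytest.approx(1 / 3)

    def test_count_breaks_fraction_ties(self, categorized_network):
        # both clusters at frac 0.5; the 2-novel cluster outranks the 1-novel
        clusters = [cluster("S", {"a1", "k1"}),
                    cluster("L", {"a2", "a3", "k2", "b1"})]
        scores = score_clusters(clusters, categorized_network)
        assert [s.cluster_id for s in scores] == ["L", "S"]
        assert scores[0].n_novel == 2

    def test_cluster_id_breaks_full_ties_and_order_invariance(
            self, categorized_network):
        clusters = [cluster("B", {"a1", "k1"}), cluster("A", {"a2", "k2"})]
        fwd = score_clusters(clusters, categorized_network)
        rev = score_clusters(clusters[::-1], categorized_network)
        assert [s.cluster_id for s in fwd] == ["A", "B"]
        assert fwd == rev

    def test_members_outside_network_ignored(self, categorized_network):
        scores = score_clusters([cluster("P", {"a1", "GHOST"})],
                                categorized_network)
        assert scores[0].n_in_network == 1

    def test_all_outside_network_dropped_with_warning(
            self, categorized_network, caplog):
        clusters = [cluster("P", {"a1"}), cluster("X", {"GHOST"})]
        with caplog.at_level("WARNING"):
            scores = score_clusters(clusters, categorized_network)
        assert [s.cluster_id for s in scores] == ["P"]
        assert "no members in the network" in caplog.text

    def test_empty_cluster_list_is_an_error(self, categorized_network):
        with pytest.raises(ValueError):
            score_clusters([], categorized_network)

    def test_isolated_node_does_not_change_ordering(self):
        cats = {"a1": CANDIDATE_ONLY, "a2": CANDIDATE_ONLY, "k1": KNOWN_ONLY}
        edges = [("a1", "a2"), ("a2", "k1")]
        clusters = [cluster("P", {"a1", "a2"}), cluster("Q", {"a2", "k1"})]
        base = score_clusters(clusters, make_network(edges, categories=cats))
        with_iso = score_clusters(
            clusters, make_network(edges, categories=cats,
                                   extra_nodes=["zzz"], hide_disconnected=False))
        assert [s.cluster_id for s in base] == [s.cluster_id for s in with_iso]

    def test_counts_bounded_by_membership(self, categorized_network):
        scores = score_clusters([cluster("P", {"a1", "k1", "b1", "GHOST"})],
                                categorized_network)
        s = scores[0]
        assert s.n_novel + s.n_known <= s.n_in_network
        assert 0 <= s.frac_novel <= 1


class TestExtractSubnetwork:
    def test_path_keeps_only_seed_neighborhood(self):
        g = make_network([("A", "B"), ("B", "C"), ("C", "D")])
        sub = extract_subnetwork(g, GeneSet("s", {"A"}))
        assert set(sub.nodes) == {"A", "B"}
        assert set(map(frozenset, sub.edges)) == {frozenset({"A", "B"})}

    def test_triangle_keeps_neighbor_neighbor_edge(self):
        # hand-enumerated induced subgraph: seeds {A} pull in B and C,
        # and the B-C edge survives because both endpoints are included
        g = make_network([("A", "B"), ("B", "C"), ("A", "C")])
        sub = extract_subnetwork(g, GeneSet("s", {"A"}))
        assert set(sub.nodes) == {"A", "B", "C"}
        assert sub.number_of_edges() == 3

    def test_absent_seeds_dropped_with_warning(self, caplog):
        g = make_network([("A", "B")])
        with caplog.at_level("WARNING"):
            sub = extract_subnetwork(g, GeneSet("s", {"A", "GHOST"}))
        assert "GHOST" in caplog.text and "A" in sub

    def test_no_present_seed_is_an_error(self):
        g = make_network([("A", "B")])
        with pytest.raises(ValueError):
            extract_subnetwork(g, GeneSet("s", {"GHOST"}))

    def test_subnetwork_contained_in_parent(self, categorized_network):
        sub = extract_subnetwork(categorized_network, GeneSet("s", {"a1", "k1"}))
        assert set(sub.nodes) <= set(categorized_network.nodes)
        assert set(map(frozenset, sub.edges)) <= set(
            map(frozenset, categorized_network.edges))
        seeds = {"a1", "k1"}
        for n in sub.nodes:
            assert n in seeds or any(
                m in seeds for m in categorized_network.neighbors(n))

    def test_categories_carried_over(self, categorized_network):
        sub = extract_subnetwork(categorized_network, GeneSet("s", {"a1"}))
        assert sub.nodes["a1"]["category"] == CANDIDATE_ONLY


class TestClusterTableIO:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "clusters.tsv"
        p.write_text("cluster_id\tname\tmembers\n"
                     "CL:1\talpha\tA,B,C\n"
                     "CL:2\tbeta\tD\n")
        out = read_cluster_table(p)
        assert out[0].members == {"A", "B", "C"}
        assert out[1].cluster_id == "CL:2"

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "clusters.tsv"
        p.write_text("cluster_id\tname\tmembers\nCL:1\ta\tA\nCL:1\tb\tB\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_cluster_table(p)

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            ClusterAnnotation("CL:1", "x", frozenset())
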