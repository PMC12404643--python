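"""Edge-table parsing, induced networks and the permutation enrichment test."""

import numpy as np
import pandas as pd
import pytest

from chdprio import network as net
from chdprio.genesets import GeneSet
from tests.conftest import make_edge_store, make_network


def write_edges(tmp_path, rows, header="protein1\tprotein2\tcombined_score"):
    p = tmp_path / "edges.tsv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


class TestLoadEdgeTable:
    def test_threshold_is_inclusive_in_integer_dialect(self, tmp_path):
        p = write_edges(tmp_path, ["A\tB\t700", "A\tC\t699"])
        store = net.load_edge_table(p, 0.7)
        assert len(store) == 1
        assert store.frame.iloc[0][["protein_a", "protein_b"]].tolist() == ["A", "B"]

    def test_real_dialect_passes_through(self, tmp_path):
        p = write_edges(tmp_path, ["A\tB\t0.9", "A\tC\t0.2"])
        store = net.load_edge_table(p, 0.7)
        assert store.frame["combined_score"].tolist() == [0.9]

    def test_symmetric_duplicates_collapse(self, tmp_path):
        p = write_edges(tmp_path, ["A\tB\t0.9", "B\tA\t0.9"])
        assert len(net.load_edge_table(p, 0.0)) == 1

    def test_self_loop_dropped_with_warning(self, tmp_path, caplog):
        p = write_edges(tmp_path, ["A\tA\t0.95", "A\tB\t0.9"])
        with caplog.at_level("WARNING"):
            store = net.load_edge_table(p, 0.0)
        assert len(store) == 1
        assert "self-loop" in caplog.text

    def test_malformed_score_reports_row(self, tmp_path):
        p = write_edges(tmp_path, ["A\tB\t0.9", "A\tC\toops"])
        with pytest.raises(ValueError, match="row 2"):
            net.load_edge_table(p, 0.0)

    def test_unknown_dialect_rejected(self, tmp_path):
        p = write_edges(tmp_path, ["A\tB\t2000"])
        with pytest.raises(ValueError, match="dialect"):
            net.load_edge_table(p, 0.0)

    def test_missing_columns_rejected(self, tmp_path):
        p = write_edges(tmp_path, ["A\tB"], header="protein1\tprotein2")
        with pytest.raises(ValueError, match="columns"):
            net.load_edge_table(p, 0.0)


class TestInduceNetwork:
    def test_hide_disconnected_drops_isolated_query_genes(self):
        g = make_network([("A", "B")], extra_nodes=["C"], hide_disconnected=True)
        assert set(g.nodes) == {"A", "B"}
        g2 = make_network([("A", "B")], extra_nodes=["C"], hide_disconnected=False)
        assert set(g2.nodes) == {"A", "B", "C"}

    def test_disjoint_query_yields_empty_network(self, caplog):
        store = make_edge_store([("X", "Y", 0.9)])
        with caplog.at_level("WARNING"):
            g = net.induce_network(GeneSet("q", {"A", "B"}), {}, store)
        assert g.number_of_nodes() == 0
        assert "empty" in caplog.text

    def test_categories_attached_with_neighbor_default(self):
        g = make_network([("A", "B")], categories={"A": "known_only"})
        assert g.nodes["A"]["category"] == "known_only"
        assert g.nodes["B"]["category"] == net.NEIGHBOR

    def test_threshold_monotonicity(self):
        """Raising the confidence cutoff never adds nodes or edges."""
        rng = np.random.default_rng(5)
        rows = []
        genes = [f"G{i}" for i in range(30)]
        for _ in range(120):
            a, b = rng.choice(genes, 2, replace=False)
            rows.append((a, b, float(rng.random())))
        df = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
        query = GeneSet("q", frozenset(genes))
        prev_nodes = prev_edges = float("inf")
        for thr in np.linspace(0, 1, 10):
            g = net.induce_network(query, {}, net.edges_from_frame(df.copy(), thr))
            assert g.number_of_nodes() <= prev_nodes
            assert g.number_of_edges() <= prev_edges
            prev_nodes, prev_edges = g.number_of_nodes(), g.number_of_edges()

    def test_handshake_lemma(self, bundle):
        from chdprio.genesets import categorize, intersect, union_dedup
        from chdprio import constraint as cn
        entries = cn.assign_deciles(bundle.constraint_table)
        cand = intersect(cn.select_top_deciles(entries, 2),
                         union_dedup(bundle.expression_sets))
        store = net.edges_from_frame(bundle.edge_frame, 0.7)
        g = net.induce_network(union_dedup([cand, bundle.known]),
                               categorize(cand, bundle.known), store)
        assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()


class TestDegreeDistribution:
    @pytest.mark.parametrize("edges, extra, expected", [
        ([("A", "B"), ("B", "C"), ("A", "C")], [], {2: 3}),   # triangle
        ([("A", "B")], ["C"], {1: 2}),                        # hidden isolated
        ([], ["A"], {}),                                      # empty network
    ])
    def test_examples(self, edges, extra, expected):
        g = make_network(edges, extra_nodes=extra)
        hist = net.degree_distribution(g)
        assert hist == expected
        assert sum(hist.values()) == g.number_of_nodes()


def sparse_background_with_clique(n=100, clique=10, p=0.02, seed=3):
    rng = np.random.default_rng(seed)
    genes = [f"P{i:03d}" for i in range(n)]
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                rows.append((genes[i], genes[j], 0.9))
    for i in range(clique):
        for j in range(i + 1, clique):
            rows.append((genes[i], genes[j], 0.95))
    df = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
    return net.edges_from_frame(df, 0.7), genes


class TestPpiEnrichment:
    def test_planted_clique_hits_the_permutation_floor(self):
        store, genes = sparse_background_with_clique()
        query = GeneSet("clique", frozenset(genes[:10]))
        g = net.induce_network(query, {}, store)
        assert g.number_of_edges() >= 45  # the clique itself
        res = net.ppi_enrichment_p(g, store, n_perm=999, seed=42)
        assert res["p_perm"] == pytest.approx(1 / 1000)
        # independent bound: a uniform draw of 10 from 100 nearly never
        # reproduces >= 45 induced edges in a ~p=0.02 background
        assert res["null_mean"] < 5

    def test_whole_background_query_gives_p_one(self):
        store, _genes = sparse_background_with_clique(n=30, clique=5)
        g = net.induce_network(GeneSet("all", store.proteins), {}, store,
                               hide_disconnected=False)
        res = net.ppi_enrichment_p(g, store, n_perm=100, seed=0)
        assert res["p_perm"] == pytest.approx(1.0)

    def test_zero_observed_edges_gives_p_one(self):
        store, genes = sparse_background_with_clique(n=30, clique=5, seed=9)
        g = net.induce_network(GeneSet("none", {"ZZZ"}), {}, store)
        res = net.ppi_enrichment_p(g, store, n_perm=100, seed=0)
        assert res["observed_edges"] == 0 and res["p_perm"] == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        store, genes = sparse_background_with_clique()
        g = net.induce_network(GeneSet("q", frozenset(genes[:15])), {}, store)
        r1 = net.ppi_enrichment_p(g, store, n_perm=199, seed=7)
        r2 = net.ppi_enrichment_p(g, store, n_perm=199, seed=7)
        assert r1 == r2

    def test_background_smaller_than_network_rejected(self):
        store, genes = sparse_background_with_clique(n=20, clique=4)
        g = net.induce_network(GeneSet("q", frozenset(genes)), {}, store,
                               hide_disconnected=False)
        small = make_edge_store([("A", "B", 0.9)])
        with pytest.raises(ValueError):
            net.ppi_enrichment_p(g, small, n_perm=100, seed=0)

    def test_degree_binned_mode_runs(self):
        store, genes = sparse_background_with_clique()
        g = net.induce_network(GeneSet("q", frozenset(genes[:10])), {}, store)
        res = net.ppi_enrichment_p(g, store, n_perm=100, seed=1,
                                   degree_binned=True)
        assert 0 < res["p_perm"] <= 1
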