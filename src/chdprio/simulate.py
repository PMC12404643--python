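"""Synthetic input bundles with planted ground truth.

The generator emits a complete, fully in-silico set of pipeline inputs
with the statistical structure the analysis assumes:

* a genome of genes with heavy-tailed constraint (s_het) scores drawn
  from a two-component beta mixture, so the top-decile selection is a
  meaningful filter;
* a planted disease module whose genes preferentially land in the top
  constraint deciles and in the cardiac-expression gene set;
* case/control flagged-gene lists (de novo variant carriers) with the
  module flagged at an elevated rate in cases only;
* a two-block stochastic-block-model PPI edge table (dense inside the
  module, sparse elsewhere) scored on the STRING 0-1000 integer scale
  so a configurable fraction of edges survive the confidence cutoff;
* cluster annotations containing one planted novel-candidate-rich
  cluster among mostly-known background clusters; and
* term annotations with a few terms planted to over-represent module
  genes.

Everything derives from a single integer seed through named
sub-streams, so bundles are bit-identical across runs.  A truth record
lists the planted structure for downstream recovery scoring.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from chdprio import constraint as cn
from chdprio import network as net
from chdprio.clusters import ClusterAnnotation, ClusterScore
from chdprio.enrichment import EnrichmentResult
from chdprio.genesets import CANDIDATE_ONLY, GeneSet, categorize, intersect, union_dedup

_STREAMS = ("shet", "module", "expression", "known", "dnv", "edges",
            "clusters", "terms")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic bundle.

    Defaults describe a desk-scale genome with a 40-gene planted
    disease module whose members are highly constrained and expressed
    with probability 0.9 each, flagged in cases at 8x the background
    de novo rate, and wired at stochastic-block-model density 0.35
    inside the module versus 0.003 background.
    """

    n_genes: int = 2000
    # constraint-score mixture (beta components; heavy right tail)
    fraction_constrained: float = 0.2
    beta_constrained: tuple[float, float] = (4.0, 6.0)
    beta_background: tuple[float, float] = (0.5, 10.0)
    top_k_deciles: int = 2
    # planted disease module
    n_module: int = 40
    p_module_high_constraint: float = 0.9
    p_module_expressed: float = 0.9
    # known disease genes
    n_known: int = 60
    fraction_known_in_module: float = 0.4
    # cardiac expression set
    expression_set_size: int = 300
    # flagged (de novo variant) gene lists
    dnv_base_rate: float = 0.02
    dnv_enrichment: float = 8.0
    # PPI edge table
    p_edge_background: float = 0.003
    p_edge_module: float = 0.35
    fraction_high_confidence: float = 0.9
    score_threshold: float = 0.7
    # cluster annotations
    n_clusters: int = 12
    cluster_size_range: tuple[int, int] = (5, 12)
    planted_cluster_size: int = 10
    planted_novel_fraction: float = 0.8
    background_novel_fraction_max: float = 0.3
    # term annotations
    n_terms: int = 40
    term_size_range: tuple[int, int] = (10, 60)
    n_planted_terms: int = 3
    planted_term_module_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.fraction_constrained, self.p_module_high_constraint,
                 self.p_module_expressed, self.fraction_known_in_module,
                 self.dnv_base_rate, self.p_edge_background, self.p_edge_module,
                 self.fraction_high_confidence, self.planted_novel_fraction,
                 self.background_novel_fraction_max,
                 self.planted_term_module_fraction]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probability parameters must lie in [0, 1]")
        if self.p_edge_module < self.p_edge_background:
            raise ValueError("within-module edge probability must be >= background")
        if self.n_module > self.n_genes:
            raise ValueError("planted module larger than the genome")
        if self.n_known > self.n_genes:
            raise ValueError("more known genes than genes")


@dataclass
class SyntheticBundle:
    """In-memory bundle plus rendered file texts and the truth record."""

    config: SyntheticConfig
    files: dict[str, str]          # file name -> text content
    truth: dict = field(default_factory=dict)
    # parsed views, for direct in-memory use
    constraint_table: pd.DataFrame | None = None
    known: GeneSet | None = None
    expression_sets: list[GeneSet] = field(default_factory=list)
    dnv_cases: GeneSet | None = None
    dnv_controls: GeneSet | None = None
    edge_frame: pd.DataFrame | None = None
    cluster_annotations: list[ClusterAnnotation] = field(default_factory=list)
    term_sets: list[GeneSet] = field(default_factory=list)

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.files):
            h.update(name.encode())
            h.update(self.files[name].encode())
        return h.hexdigest()

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write every file plus a manifest with per-file checksums."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        checksums = {}
        for name, text in self.files.items():
            (outdir / name).write_text(text)
            checksums[name] = hashlib.sha256(text.encode()).hexdigest()
        manifest = {
            "config": asdict(self.config),
            "seed": self.config.seed,
            "fingerprint": self.fingerprint,
            "checksums": checksums,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2))
        return checksums


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _gmt_text(sets: list[GeneSet]) -> str:
    return "\n".join("\t".join([s.label, "synthetic", *s.sorted()]) for s in sets) + "\n"


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a complete synthetic input bundle; deterministic per seed."""
    rng = _rngs(config.seed)
    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])

    # --- constraint scores -------------------------------------------------
    constrained_latent = rng["shet"].random(config.n_genes) < config.fraction_constrained
    a_c, b_c = config.beta_constrained
    a_b, b_b = config.beta_background
    s_het = np.where(constrained_latent,
                     rng["shet"].beta(a_c, b_c, config.n_genes),
                     rng["shet"].beta(a_b, b_b, config.n_genes))

    module_idx = rng["module"].choice(config.n_genes, config.n_module, replace=False)
    module_genes = sorted(genes[module_idx])
    forced_high = rng["module"].random(config.n_module) < config.p_module_high_constraint
    # place forced module genes above the empirical top-decile boundary
    q = float(np.quantile(s_het, 1 - config.top_k_deciles / cn.N_DECILES))
    u = rng["module"].uniform(0.02, 0.98, config.n_module)
    forced_vals = q + u * (1.0 - q)
    s_het[module_idx[forced_high]] = forced_vals[forced_high]
    constrained_latent[module_idx] = forced_high

    constraint_table = pd.DataFrame({"gene": genes, "s_het": np.round(s_het, 6)})
    entries = cn.assign_deciles(constraint_table)
    top_set = cn.select_top_deciles(entries, config.top_k_deciles, label="high_constraint")

    # --- expression sets ---------------------------------------------------
    expressed_module = [g for g, keep in zip(
        genes[module_idx],
        rng["expression"].random(config.n_module) < config.p_module_expressed) if keep]
    non_module = np.setdiff1d(genes, genes[module_idx])
    n_fill = max(config.expression_set_size - len(expressed_module), 0)
    fill = rng["expression"].choice(non_module, size=min(n_fill, len(non_module)),
                                    replace=False)
    expressed = sorted(set(expressed_module) | set(fill))
    # split into two overlapping source sets, as with two expression studies
    mask = rng["expression"].random(len(expressed)) < 0.6
    set_a = {g for g, m in zip(expressed, mask) if m}
    set_b = set(expressed) - set_a
    overlap = rng["expression"].choice(sorted(set_a) or expressed,
                                       size=max(1, len(set_a) // 5), replace=False)
    set_b |= set(overlap)
    expression_sets = [GeneSet("cardiac_lineage_a", frozenset(set_a)),
                       GeneSet("cardiac_lineage_b", frozenset(set_b))]
    expressed_set = union_dedup(expression_sets)

    # --- known disease genes ----------------------------------------------
    n_known_mod = min(round(config.n_known * config.fraction_known_in_module),
                      config.n_module)
    known_mod = rng["known"].choice(sorted(module_genes), size=n_known_mod,
                                    replace=False)
    known_bg = rng["known"].choice(non_module, size=config.n_known - n_known_mod,
                                   replace=False)
    known = GeneSet("known_disease_genes", frozenset(known_mod) | frozenset(known_bg))

    # --- flagged gene lists (cases enriched in the module) -----------------
    module_set = set(module_genes)
    rate_case = np.array([
        min(1.0, config.dnv_base_rate * (config.dnv_enrichment if g in module_set else 1.0))
        for g in genes])
    case_mask = rng["dnv"].random(config.n_genes) < rate_case
    control_mask = rng["dnv"].random(config.n_genes) < config.dnv_base_rate
    dnv_cases = GeneSet("dnv_cases", frozenset(genes[case_mask]))
    dnv_controls = GeneSet("dnv_controls", frozenset(genes[control_mask]))

    # --- PPI edge table (two-block SBM) ------------------------------------
    ss = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))[5]
    g_seed, m_seed = (int(x) for x in ss.generate_state(2) % (2**31))
    g_bg = nx.fast_gnp_random_graph(config.n_genes, config.p_edge_background,
                                    seed=g_seed)
    pairs = {tuple(sorted((int(a), int(b)))) for a, b in g_bg.edges()}
    g_mod = nx.fast_gnp_random_graph(config.n_module, config.p_edge_module,
                                     seed=m_seed)
    sorted_module_idx = np.sort(module_idx)
    for a, b in g_mod.edges():
        pairs.add(tuple(sorted((int(sorted_module_idx[a]), int(sorted_module_idx[b])))))
    pair_list = sorted(pairs)
    high = rng["edges"].random(len(pair_list)) < config.fraction_high_confidence
    scores = np.where(high,
                      rng["edges"].uniform(config.score_threshold, 1.0, len(pair_list)),
                      rng["edges"].uniform(0.15, config.score_threshold - 0.001,
                                           len(pair_list)))
    edge_frame = pd.DataFrame({
        "protein1": [genes[a] for a, _ in pair_list],
        "protein2": [genes[b] for _, b in pair_list],
        "combined_score": np.round(scores * 1000).astype(int),
    })

    # --- the generator's own view of the induced network -------------------
    candidates = intersect(top_set, expressed_set)
    categories = categorize(candidates, known)
    store = net.edges_from_frame(edge_frame, config.score_threshold)
    query = union_dedup([candidates, known])
    graph = net.induce_network(query, categories, store, hide_disconnected=True)
    novel_nodes = sorted(n for n in graph if graph.nodes[n]["category"] == CANDIDATE_ONLY)
    known_nodes = sorted(n for n in graph if graph.nodes[n]["category"] != CANDIDATE_ONLY)
    novel_module_nodes = [n for n in novel_nodes if n in module_set]
    known_module_nodes = [n for n in known_nodes if n in module_set]

    # --- cluster annotations ------------------------------------------------
    crng = rng["clusters"]
    n_novel_target = round(config.planted_cluster_size * config.planted_novel_fraction)
    planted_novel = novel_module_nodes[:n_novel_target]
    if len(planted_novel) < n_novel_target:  # thin module: top up from any novel node
        extra = [n for n in novel_nodes if n not in planted_novel]
        planted_novel += extra[:n_novel_target - len(planted_novel)]
    n_known_target = config.planted_cluster_size - len(planted_novel)
    planted_known = (known_module_nodes + [n for n in known_nodes
                                           if n not in known_module_nodes])[:n_known_target]
    planted_members = frozenset(planted_novel) | frozenset(planted_known)

    lo, hi = config.cluster_size_range
    cluster_members: list[frozenset[str]] = []
    for _ in range(config.n_clusters - 1):
        size = int(crng.integers(lo, hi + 1))
        n_novel = int(np.floor(size * crng.uniform(0, config.background_novel_fraction_max)))
        n_kn = size - n_novel
        kn_pool = known_nodes if known_nodes else novel_nodes
        members = set(crng.choice(kn_pool, size=min(n_kn, len(kn_pool)), replace=False))
        if n_novel and novel_nodes:
            members |= set(crng.choice(novel_nodes, size=min(n_novel, len(novel_nodes)),
                                       replace=False))
        if members:
            cluster_members.append(frozenset(members))
    order = list(crng.permutation(len(cluster_members) + 1))
    planted_pos = order.index(len(cluster_members))
    all_members = cluster_members + [planted_members]
    clusters = []
    planted_cluster_id = ""
    for rank, pos in enumerate(order):
        cid = f"CL:{rank + 1:04d}"
        name = ("planted module cluster" if pos == len(cluster_members)
                else f"background cluster {pos + 1}")
        if pos == len(cluster_members):
            planted_cluster_id = cid
        clusters.append(ClusterAnnotation(cid, name, all_members[pos]))

    # --- term annotations ----------------------------------------------------
    trng = rng["terms"]
    t_lo, t_hi = config.term_size_range
    term_sets: list[GeneSet] = []
    planted_term_ids: list[str] = []
    planted_slots = set(trng.choice(config.n_terms, config.n_planted_terms,
                                    replace=False).tolist())
    for i in range(config.n_terms):
        tid = f"T{i + 1:04d}"
        size = int(trng.integers(t_lo, t_hi + 1))
        if i in planted_slots:
            n_mod = min(round(size * config.planted_term_module_fraction),
                        len(module_genes))
            mod_part = trng.choice(sorted(module_genes), size=n_mod, replace=False)
            bg_part = trng.choice(non_module, size=size - n_mod, replace=False)
            members = frozenset(mod_part) | frozenset(bg_part)
            planted_term_ids.append(tid)
        else:
            members = frozenset(trng.choice(genes, size=size, replace=False))
        term_sets.append(GeneSet(tid, members))

    # --- render files --------------------------------------------------------
    buf = io.StringIO()
    constraint_table.to_csv(buf, sep="\t", index=False)
    files = {
        "constraint.tsv": buf.getvalue(),
        "known.gmt": _gmt_text([known]),
        "expression.gmt": _gmt_text(expression_sets),
        "dnv_cases.txt": "\n".join(dnv_cases.sorted()) + "\n",
        "dnv_controls.txt": "\n".join(dnv_controls.sorted()) + "\n",
        "edges.tsv": edge_frame.to_csv(sep="\t", index=False),
        "clusters.tsv": "cluster_id\tname\tmembers\n" + "".join(
            f"{c.cluster_id}\t{c.name}\t{','.join(sorted(c.members))}\n"
            for c in clusters),
        "terms.gmt": _gmt_text(term_sets),
    }

    truth = {
        "seed": config.seed,
        "module_genes": list(module_genes),
        "planted_cluster_id": planted_cluster_id,
        "planted_term_ids": planted_term_ids,
        "latent": {
            str(g): {
                "constrained": bool(c),
                "expressed": g in expressed_set.members,
                "flagged": g in dnv_cases.members,
                "in_module": g in module_set,
            }
            for g, c in zip(genes, constrained_latent)
        },
    }

    return SyntheticBundle(
        config=config, files=files, truth=truth,
        constraint_table=constraint_table, known=known,
        expression_sets=expression_sets, dnv_cases=dnv_cases,
        dnv_controls=dnv_controls, edge_frame=edge_frame,
        cluster_annotations=clusters, term_sets=term_sets,
    )


def truth_report(bundle: SyntheticBundle, candidate_set: GeneSet,
                 cluster_scores: list[ClusterScore] | None = None,
                 enrichment: list[EnrichmentResult] | None = None,
                 fingerprint: str | None = None) -> dict:
    """Recovery metrics of pipeline outputs against the planted truth.

    ``fingerprint``, when supplied by the pipeline run, must match the
    bundle's own fingerprint, guarding against scoring outputs from a
    different seed.  Precision is NaN when the candidate set is empty.
    """
    if fingerprint is not None and fingerprint != bundle.fingerprint:
        raise ValueError("output fingerprint does not match this bundle "
                         "(different seed or inputs)")
    module = set(bundle.truth["module_genes"])
    hits = module & candidate_set.members
    recall = len(hits) / len(module) if module else float("nan")
    precision = (len(hits) / len(candidate_set)
                 if len(candidate_set) else float("nan"))
    report = {"module_recall": recall, "module_precision": precision,
              "n_candidates": len(candidate_set)}
    if cluster_scores is not None:
        ranks = {s.cluster_id: i + 1 for i, s in enumerate(cluster_scores)}
        report["planted_cluster_rank"] = ranks.get(
            bundle.truth["planted_cluster_id"])
    if enrichment is not None:
        term_ranks = {r.term_id: i + 1 for i, r in enumerate(enrichment)}
        report["planted_term_ranks"] = {
            t: term_ranks.get(t) for t in bundle.truth["planted_term_ids"]}
    return report
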