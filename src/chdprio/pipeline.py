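"""End-to-end orchestration: derive candidates, build the network,
score clusters, extract the top subnetwork and run term enrichment.

The set-algebra core (decile selection, expression union, candidate
intersection, categorization) runs from the constraint/expression/known
tables alone.  Network, cluster and enrichment stages are optional:
when their input files are absent the stage is marked SKIPPED rather
than failing the run, so the pipeline degrades gracefully to whatever
inputs are available.  Every run writes a JSON manifest with input
checksums, parameters, the seed and per-stage status.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from chdprio import __version__
from chdprio import constraint as cn
from chdprio import network as net
from chdprio.catalog import OrthologMap, map_orthologs
from chdprio.clusters import (ClusterScore, extract_subnetwork, read_cluster_table,
                              score_clusters, write_cluster_scores)
from chdprio.enrichment import (annotations_from_gmt, enrich_terms,
                                write_enrichment)
from chdprio.genesets import (GeneSet, categorize, intersect, overlap_significance,
                              read_gene_list, read_gmt, union_dedup,
                              write_gene_list)

logger = logging.getLogger(__name__)

#: published overlap counts used by the optional integration checks:
#: candidate genes carrying damaging de novo variants in cases, and
#: candidate genes expressed in human embryonic heart tissue
PUBLISHED_DNV_OVERLAP = 44
PUBLISHED_HEART_EXPRESSION_OVERLAP = 154

OK, SKIPPED, FAILED = "OK", "SKIPPED", "FAILED"


@dataclass
class RunConfig:
    """Inputs and parameters for a full pipeline run."""

    constraint_path: str
    expression_gmt: str
    known_gmt: str
    outdir: str
    ortholog_path: str | None = None
    dnv_cases_path: str | None = None
    edges_path: str | None = None
    clusters_path: str | None = None
    annotations_gmt: str | None = None
    top_k_deciles: int = 2
    score_threshold: float = net.HIGH_CONFIDENCE
    n_perm: int = 999
    min_hits: int = 2
    universe: str = "constraint"  # or "annotation"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.top_k_deciles <= 10:
            raise ValueError("top_k_deciles must be in 1..10")
        if not 0 <= self.score_threshold <= 1:
            raise ValueError("score_threshold must be in [0, 1]")
        if self.universe not in ("constraint", "annotation"):
            raise ValueError("universe must be 'constraint' or 'annotation'")
        for name in ("constraint_path", "expression_gmt", "known_gmt"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    stages: dict[str, str]
    manifest: dict
    candidates: GeneSet | None = None
    categories: dict[str, str] = field(default_factory=dict)
    burden: cn.BurdenResult | None = None
    network: object | None = None
    cluster_scores: list[ClusterScore] = field(default_factory=list)
    subnetwork: object | None = None
    enrichment: list = field(default_factory=list)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_all(config: RunConfig) -> PipelineResult:
    """Execute every stage in dependency order and write all outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, str] = {}
    result = PipelineResult(stages=stages, manifest={})
    manifest: dict = {
        "parameters": {k: v for k, v in asdict(config).items()},
        "version": __version__,
        "inputs": {},
    }
    for name in ("constraint_path", "expression_gmt", "known_gmt",
                 "ortholog_path", "dnv_cases_path", "edges_path",
                 "clusters_path", "annotations_gmt"):
        p = getattr(config, name)
        if p and Path(p).exists():
            manifest["inputs"][name] = _checksum(p)

    def finish(stage: str | None = None, error: Exception | None = None):
        if stage is not None:
            stages[stage] = FAILED
            manifest["error"] = f"stage {stage}: {error}"
        manifest["stages"] = stages
        result.manifest = manifest
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         default=str))

    current = "derive_candidates"
    try:
        # --- candidate derivation ---------------------------------------
        entries = cn.entries_from_tsv(config.constraint_path)
        top = cn.select_top_deciles(entries, config.top_k_deciles,
                                    label="high_constraint")
        expression_sets = read_gmt(config.expression_gmt)
        if config.ortholog_path:
            om = OrthologMap.from_tsv(config.ortholog_path)
            mapped = []
            for s in expression_sets:
                ms, rep = map_orthologs(s, om)
                logger.info("ortholog mapping %s: %d unmapped, %d one-to-many",
                            s.label, rep["n_unmapped"], rep["n_one_to_many"])
                mapped.append(ms)
            expression_sets = mapped
        expressed = union_dedup(expression_sets)
        candidates = GeneSet("candidates", intersect(top, expressed).members)
        known = union_dedup(read_gmt(config.known_gmt))
        categories = categorize(candidates, known)
        universe_n = len({e.gene for e in entries})
        overlap = overlap_significance(candidates, known, universe_n)
        write_gene_list(candidates, outdir / "candidates.txt")
        with open(outdir / "categories.tsv", "w") as fh:
            fh.write("gene\tcategory\n")
            for g in sorted(categories):
                fh.write(f"{g}\t{categories[g]}\n")
        manifest["candidates"] = {
            "n_high_constraint": len(top), "n_expressed": len(expressed),
            "n_candidates": len(candidates), "n_known": len(known),
            "n_overlap_known": overlap["k"],
            "overlap_expected": overlap["expected"],
            "overlap_p_hyper": overlap["p_hyper"],
        }
        result.candidates, result.categories = candidates, categories
        stages[current] = OK

        # --- burden test -------------------------------------------------
        current = "burden"
        if config.dnv_cases_path and Path(config.dnv_cases_path).exists():
            flagged = read_gene_list(config.dnv_cases_path)
            burden = cn.decile_burden_test(entries, flagged)
            burden.per_decile.to_csv(outdir / "burden_per_decile.tsv",
                                     sep="\t", index=False)
            stats = {"anova_F": burden.anova_F, "anova_p": burden.anova_p,
                     "trend_chi2": burden.trend_chi2, "trend_p": burden.trend_p}
            (outdir / "burden_stats.json").write_text(
                json.dumps(stats, indent=2))
            manifest["burden"] = stats
            result.burden = burden
            stages[current] = OK
        else:
            stages[current] = SKIPPED

        # --- network -----------------------------------------------------
        current = "network"
        graph = None
        store = None
        if config.edges_path and Path(config.edges_path).exists():
            store = net.load_edge_table(config.edges_path, config.score_threshold)
            query = union_dedup([candidates, known])
            graph = net.induce_network(query, categories, store,
                                       hide_disconnected=True)
            net.write_network(graph, outdir / "network_edges.tsv",
                              outdir / "network_nodes.tsv")
            enr = net.ppi_enrichment_p(graph, store, n_perm=config.n_perm,
                                       seed=config.seed)
            manifest["network"] = {
                "n_nodes": graph.number_of_nodes(),
                "n_edges": graph.number_of_edges(), **enr,
            }
            result.network = graph
            stages[current] = OK
        else:
            stages[current] = SKIPPED

        # --- cluster scoring + subnetwork ---------------------------------
        current = "clusters"
        if (config.clusters_path and Path(config.clusters_path).exists()
                and graph is not None and graph.number_of_nodes() > 0):
            annotations = read_cluster_table(config.clusters_path)
            scores = score_clusters(annotations, graph)
            write_cluster_scores(scores, outdir / "cluster_scores.tsv")
            result.cluster_scores = scores
            manifest["clusters"] = {
                "n_scored": len(scores),
                "top_cluster": scores[0].cluster_id if scores else None,
            }
            stages[current] = OK
            current = "subnetwork"
            if scores:
                top_cluster = next(c for c in annotations
                                   if c.cluster_id == scores[0].cluster_id)
                seeds = GeneSet(top_cluster.cluster_id, top_cluster.members)
                sub = extract_subnetwork(graph, seeds)
                net.write_network(sub, outdir / "subnetwork_edges.tsv",
                                  outdir / "subnetwork_nodes.tsv")
                manifest["subnetwork"] = {
                    "seed_cluster": top_cluster.cluster_id,
                    "n_nodes": sub.number_of_nodes(),
                    "n_edges": sub.number_of_edges(),
                }
                result.subnetwork = sub
                stages[current] = OK
            else:
                stages[current] = SKIPPED
        else:
            stages[current] = SKIPPED
            stages["subnetwork"] = SKIPPED

        # --- term enrichment ----------------------------------------------
        current = "term_enrichment"
        if config.annotations_gmt and Path(config.annotations_gmt).exists():
            terms = annotations_from_gmt(read_gmt(config.annotations_gmt))
            if config.universe == "constraint":
                universe = GeneSet("scored_genes",
                                   frozenset(e.gene for e in entries))
            else:
                universe = None
            results = enrich_terms(candidates, terms, universe=universe,
                                   min_hits=config.min_hits)
            write_enrichment(results, outdir / "enrichment.tsv")
            result.enrichment = results
            manifest["term_enrichment"] = {
                "n_tested": len(results),
                "top_term": results[0].term_id if results else None,
            }
            stages[current] = OK
        else:
            stages[current] = SKIPPED
    except Exception as exc:
        finish(current, exc)
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    finish()
    return result


def published_overlap_checks(candidates: GeneSet,
                             dnv_cases_path: str | Path | None = None,
                             heart_expression_path: str | Path | None = None
                             ) -> list[dict]:
    """Integration checks against third-party supplement files.

    Each check reports REPRODUCED / MISMATCH when the corresponding
    file is supplied, and SKIPPED otherwise: the overlap of the
    candidate list with case de novo variant genes (published count 44)
    and with human embryonic-heart-expressed genes (published count
    154).  The files are large third-party supplements and are never
    bundled; desk runs simply skip.
    """
    checks = []
    for label, path, expected in (
            ("dnv_case_overlap", dnv_cases_path, PUBLISHED_DNV_OVERLAP),
            ("heart_expression_overlap", heart_expression_path,
             PUBLISHED_HEART_EXPRESSION_OVERLAP)):
        if path is None or not Path(path).exists():
            checks.append({"check": label, "status": SKIPPED,
                           "observed": None, "expected": expected})
            continue
        other = read_gene_list(path)
        observed = len(candidates.members & other.members)
        status = "REPRODUCED" if observed == expected else "MISMATCH"
        checks.append({"check": label, "status": status,
                       "observed": observed, "expected": expected})
    return checks
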