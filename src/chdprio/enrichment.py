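"""Term over-representation with Bonferroni adjustment.

Flat annotation model (no ontology-graph propagation): each term simply
annotates a set of genes.  For a query of n genes drawn from a universe
of N genes of which K carry a term, the raw p-value is the upper-tail
hypergeometric probability of seeing at least the observed k hits.
Bonferroni multiplies by the number of terms actually tested (those
with at least ``min_hits`` query hits), mirroring the common practice
of correcting only over represented terms.

An optional EASE mode penalizes one hit (upper tail at k-1), the
jackknifed variant used by the DAVID annotation server.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from chdprio.genesets import GeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermAnnotation:
    term_id: str
    term_name: str
    annotated_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.annotated_genes:
            raise ValueError(f"term {self.term_id} annotates no genes")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int                  # query hits
    K: int                  # annotated genes in the universe
    n: int                  # query size (restricted to the universe)
    N: int                  # universe size
    fold_enrichment: float  # (k/n) / (K/N)
    p_raw: float
    p_bonferroni: float


def annotations_from_gmt(sets: list[GeneSet]) -> list[TermAnnotation]:
    """Interpret GMT gene sets as term annotations (label = id = name)."""
    return [TermAnnotation(s.label, s.label, s.members) for s in sets]


def default_universe(annotations: list[TermAnnotation]) -> GeneSet:
    members: frozenset[str] = frozenset()
    for t in annotations:
        members |= t.annotated_genes
    return GeneSet("annotation_universe", members)


def enrich_terms(query: GeneSet, annotations: list[TermAnnotation],
                 universe: GeneSet | None = None, min_hits: int = 2,
                 ease: bool = False) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term in the query.

    Query genes outside the universe are dropped with a warning.  Only
    terms with at least ``min_hits`` query hits are tested; m_tested is
    the Bonferroni multiplier.  Results are sorted by raw p-value, then
    term_id.
    """
    if not annotations:
        raise ValueError("empty annotation list")
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    if universe is None:
        universe = default_universe(annotations)
    if len(universe) == 0:
        raise ValueError("empty universe")
    q = query.members & universe.members
    dropped = len(query) - len(q)
    if dropped:
        logger.warning("%d query gene(s) outside the universe dropped", dropped)
    N, n = len(universe), len(q)

    tested: list[tuple[TermAnnotation, int, int]] = []
    for t in annotations:
        K = len(t.annotated_genes & universe.members)
        k = len(t.annotated_genes & q)
        if k >= min_hits:
            tested.append((t, k, K))
    m_tested = len(tested)

    results: list[EnrichmentResult] = []
    for t, k, K in tested:
        k_eff = max(k - 1, 0) if ease else k
        p_raw = float(hypergeom.sf(k_eff - 1, N, K, n))
        p_raw = min(p_raw, 1.0)
        fold = (k / n) / (K / N) if n and K else 0.0
        results.append(EnrichmentResult(
            term_id=t.term_id, term_name=t.term_name,
            k=k, K=K, n=n, N=N,
            fold_enrichment=fold, p_raw=p_raw,
            p_bonferroni=min(1.0, p_raw * m_tested),
        ))
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def write_enrichment(results: list[EnrichmentResult], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)
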