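"""Gene-set containers, set algebra, category assignment and GMT I/O.

Gene sets are plain collections of approved symbols.  All membership is
by exact (already-normalized) symbol string; there is no fuzzy matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

#: category labels used throughout the network / cluster stages
CANDIDATE_ONLY = "candidate_only"
KNOWN_ONLY = "known_only"
BOTH = "both"


@dataclass(frozen=True)
class GeneSet:
    """A labeled, deduplicated collection of gene symbols."""

    label: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))

    def sorted(self) -> list[str]:
        return sorted(self.members)


def intersect(a: GeneSet, b: GeneSet) -> GeneSet:
    """Exact intersection; the label records both parents."""
    return GeneSet(f"{a.label}&{b.label}", a.members & b.members)


def union_dedup(sets: Iterable[GeneSet]) -> GeneSet:
    """Union of one or more gene sets with duplicates removed."""
    sets = list(sets)
    if not sets:
        raise ValueError("union_dedup requires at least one gene set")
    members: frozenset[str] = frozenset()
    for s in sets:
        members |= s.members
    return GeneSet("|".join(s.label for s in sets), members)


def categorize(candidates: GeneSet, known: GeneSet) -> dict[str, str]:
    """Partition candidates ∪ known into candidate_only / known_only / both.

    The three categories mirror the halo colors of the published network:
    candidate genes, known disease genes, and genes in both lists.
    """
    out: dict[str, str] = {}
    for g in candidates.members & known.members:
        out[g] = BOTH
    for g in candidates.members - known.members:
        out[g] = CANDIDATE_ONLY
    for g in known.members - candidates.members:
        out[g] = KNOWN_ONLY
    return out


def overlap_significance(a: GeneSet, b: GeneSet, universe_n: int) -> dict[str, float]:
    """Upper-tail hypergeometric significance of the overlap |a ∩ b|.

    Models drawing |a| genes from a universe of ``universe_n`` genes of
    which |b| are successes; returns ``P(K >= k)`` where ``k = |a ∩ b|``,
    plus the expected overlap under independence.
    """
    if universe_n < len(a) or universe_n < len(b):
        raise ValueError(
            f"universe ({universe_n}) smaller than a gene set "
            f"(|a|={len(a)}, |b|={len(b)})"
        )
    k = len(a.members & b.members)
    expected = len(a) * len(b) / universe_n
    # survival function is P(K > k-1) = P(K >= k)
    p_hyper = float(hypergeom.sf(k - 1, universe_n, len(b), len(a)))
    return {"k": k, "expected": expected, "p_hyper": min(p_hyper, 1.0)}


# ---------------------------------------------------------------------------
# I/O: GMT (one set per line: name, description, members) and flat lists
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description "
                             f"and at least one member")
        name, _desc, *members = fields
        members = [m.strip() for m in members if m.strip()]
        sets.append(GeneSet(name, frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for s in sets:
        desc = (descriptions or {}).get(s.label, "na")
        lines.append("\t".join([s.label, desc, *s.sorted()]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path, label: str | None = None) -> GeneSet:
    """One symbol per line; blank lines ignored."""
    p = Path(path)
    members = frozenset(
        line.strip() for line in p.read_text().splitlines() if line.strip()
    )
    return GeneSet(label or p.stem, members)


def write_gene_list(genes: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(genes.sorted()) + "\n")
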