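"""Gene-symbol normalization and cross-species ortholog mapping.

Offline analogues of the HGNC multi-symbol checker and the HCOP
orthology-comparison tool: a symbol catalog maps aliases and previous
symbols to the current approved symbol, and an ortholog table maps
source-species symbols to sets of approved target-species symbols.
Both are loaded from TSV snapshot files; no web service is queried.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from chdprio.genesets import GeneSet

logger = logging.getLogger(__name__)

_VALID_STATUSES = {"approved", "alias", "previous", "withdrawn"}


@dataclass(frozen=True)
class CatalogRecord:
    approved_symbol: str
    status: str


class SymbolCatalog:
    """Case-insensitive lookup from any known symbol to its approved form.

    Invariants enforced at construction: every alias/previous entry
    resolves in a single step to a symbol that is itself an approved
    entry (so no alias->alias chains or cycles), approved symbols
    resolve to themselves, and no symbol is empty.
    """

    def __init__(self, entries: dict[str, CatalogRecord]):
        self._entries = entries
        self._validate()

    def _validate(self) -> None:
        approved = {
            rec.approved_symbol
            for rec in self._entries.values()
            if rec.status == "approved"
        }
        for key, rec in self._entries.items():
            if not key or not rec.approved_symbol:
                raise ValueError("catalog contains an empty symbol")
            if rec.status not in _VALID_STATUSES:
                raise ValueError(f"unknown status {rec.status!r} for {key!r}")
            if rec.status == "approved" and rec.approved_symbol.casefold() != key:
                raise ValueError(
                    f"approved symbol {key!r} does not resolve to itself"
                )
            if rec.status in ("alias", "previous") and rec.approved_symbol not in approved:
                raise ValueError(
                    f"{rec.status} symbol {key!r} points to "
                    f"{rec.approved_symbol!r}, which is not an approved entry "
                    "(alias chain or dangling reference)"
                )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SymbolCatalog":
        required = {"symbol", "approved_symbol", "status"}
        if not required.issubset(df.columns):
            raise ValueError(f"catalog table needs columns {sorted(required)}")
        entries: dict[str, CatalogRecord] = {}
        for row in df.itertuples(index=False):
            key = str(row.symbol).strip().casefold()
            if key in entries:
                raise ValueError(f"duplicate catalog symbol {row.symbol!r}")
            entries[key] = CatalogRecord(
                str(row.approved_symbol).strip(), str(row.status).strip()
            )
        return cls(entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SymbolCatalog":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))

    @classmethod
    def from_approved(cls, symbols: list[str],
                      aliases: dict[str, str] | None = None) -> "SymbolCatalog":
        """Convenience constructor: approved symbols plus alias->approved pairs."""
        entries = {
            s.casefold(): CatalogRecord(s, "approved") for s in symbols
        }
        for old, new in (aliases or {}).items():
            entries[old.casefold()] = CatalogRecord(new, "alias")
        return cls(entries)

    def resolve(self, symbol: str) -> str | None:
        """Approved symbol for ``symbol``, or None if unknown/withdrawn."""
        rec = self._entries.get(symbol.strip().casefold())
        if rec is None or rec.status == "withdrawn":
            return None
        return rec.approved_symbol

    def __len__(self) -> int:
        return len(self._entries)


def normalize_symbols(raw: list[str], catalog: SymbolCatalog,
                      label: str = "normalized") -> tuple[GeneSet, dict]:
    """Resolve raw symbols to approved symbols; dedup; report attrition.

    Unrecognized symbols are dropped with a warning (not an error),
    mirroring the attrition seen when legacy gene lists are re-checked
    against a current nomenclature snapshot.  The report satisfies
    ``n_input == n_output + n_merged_duplicates + n_unrecognized``.
    """
    if not raw:
        raise ValueError("normalize_symbols requires a non-empty input list")
    seen: set[str] = set()
    unrecognized: list[str] = []
    n_merged = 0
    for sym in raw:
        approved = catalog.resolve(sym)
        if approved is None:
            unrecognized.append(sym)
        elif approved in seen:
            n_merged += 1
        else:
            seen.add(approved)
    if unrecognized:
        logger.warning("%d symbol(s) not recognized by the catalog: %s",
                       len(unrecognized), ", ".join(unrecognized[:10]))
    report = {
        "n_input": len(raw),
        "n_output": len(seen),
        "n_merged_duplicates": n_merged,
        "n_unrecognized": len(unrecognized),
        "unrecognized": unrecognized,
    }
    return GeneSet(label, frozenset(seen)), report


class OrthologMap:
    """Source-species symbol -> set of target-species approved symbols."""

    def __init__(self, pairs: dict[str, frozenset[str]]):
        for src, targets in pairs.items():
            if not targets:
                raise ValueError(f"ortholog entry {src!r} has an empty target set")
        self._pairs = {k: frozenset(v) for k, v in pairs.items()}
        self._index = {k.casefold(): k for k in self._pairs}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"source_symbol", "target_symbol"}
        if not required.issubset(df.columns):
            raise ValueError(f"ortholog table needs columns {sorted(required)}")
        pairs: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            pairs.setdefault(str(row.source_symbol).strip(), set()).add(
                str(row.target_symbol).strip()
            )
        return cls({k: frozenset(v) for k, v in pairs.items()})

    def targets(self, symbol: str) -> frozenset[str]:
        key = self._index.get(symbol.casefold())
        return self._pairs[key] if key is not None else frozenset()

    def inverted(self) -> "OrthologMap":
        inv: dict[str, set[str]] = {}
        for src, targets in self._pairs.items():
            for t in targets:
                inv.setdefault(t, set()).add(src)
        return OrthologMap({k: frozenset(v) for k, v in inv.items()})


def map_orthologs(genes: GeneSet, orthologs: OrthologMap,
                  label: str | None = None) -> tuple[GeneSet, dict]:
    """Union of target-species orthologs over the input genes.

    One-to-many hits are all retained; genes without an entry are
    counted as unmapped and dropped.
    """
    mapped: set[str] = set()
    n_unmapped = 0
    n_one_to_many = 0
    for g in genes:
        targets = orthologs.targets(g)
        if not targets:
            n_unmapped += 1
            continue
        if len(targets) > 1:
            n_one_to_many += 1
        mapped |= targets
    report = {"n_unmapped": n_unmapped, "n_one_to_many": n_one_to_many}
    return GeneSet(label or f"{genes.label}_orthologs", frozenset(mapped)), report
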