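"""Selective-constraint (s_het) deciles and the decile burden test.

s_het is a per-gene heterozygote selection coefficient; high values mark
genes under strong constraint (haploinsufficiency).  Genes are ranked by
s_het and split into ten near-equal bins, with decile 10 holding the
most constrained genes.  The burden test asks whether a flagged gene
list (e.g., genes carrying damaging de novo variants in cases) is
concentrated in the high deciles, via a one-way ANOVA on the binary
flag grouped by decile plus a Cochran-Armitage-style chi-square test
for linear trend in the per-decile flagged proportions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from chdprio.genesets import GeneSet

logger = logging.getLogger(__name__)

N_DECILES = 10


@dataclass(frozen=True)
class ConstraintEntry:
    gene: str
    s_het: float
    decile: int  # 1 (least constrained) .. 10 (most constrained)


@dataclass(frozen=True)
class BurdenResult:
    per_decile: pd.DataFrame  # columns decile, n_genes, n_flagged, fraction_flagged
    anova_F: float
    anova_p: float
    trend_chi2: float
    trend_p: float


def assign_deciles(table: list[tuple[str, float]] | pd.DataFrame) -> list[ConstraintEntry]:
    """Rank genes by s_het ascending and split into 10 contiguous bins.

    Ties are broken by gene symbol (ascending) so the assignment is a
    deterministic function of the table contents, independent of row
    order.  With n = 10q + r genes, the r remainder genes go to the
    lowest deciles, so decile 10 always holds exactly q of the
    largest-s_het genes.
    """
    if isinstance(table, pd.DataFrame):
        pairs = list(zip(table["gene"].astype(str), table["s_het"].astype(float)))
    else:
        pairs = [(str(g), float(s)) for g, s in table]
    if len(pairs) < N_DECILES:
        raise ValueError(f"need at least {N_DECILES} genes, got {len(pairs)}")
    for g, s in pairs:
        if not math.isfinite(s):
            raise ValueError(f"non-finite s_het value for gene {g!r}")
    pairs.sort(key=lambda gs: (gs[1], gs[0]))
    n = len(pairs)
    q, r = divmod(n, N_DECILES)
    sizes = [q + 1 if d <= r else q for d in range(1, N_DECILES + 1)]
    entries: list[ConstraintEntry] = []
    i = 0
    for decile, size in zip(range(1, N_DECILES + 1), sizes):
        for g, s in pairs[i:i + size]:
            entries.append(ConstraintEntry(g, s, decile))
        i += size
    return entries


def entries_from_tsv(path: str | Path) -> list[ConstraintEntry]:
    """Load a constraint table; a pre-binned ``decile`` column overrides.

    The decile-column override exists because published constraint
    tables ship their own decile labels whose orientation may differ
    from the package's convention.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ValueError("constraint table needs a 'gene' column")
    if "decile" in df.columns:
        s_het = df["s_het"] if "s_het" in df.columns else pd.Series(
            [float("nan")] * len(df))
        return [
            ConstraintEntry(str(g), float(s), int(d))
            for g, s, d in zip(df["gene"], s_het, df["decile"])
        ]
    if "s_het" not in df.columns:
        raise ValueError("constraint table needs 's_het' and/or 'decile'")
    return assign_deciles(df)


def select_top_deciles(entries: list[ConstraintEntry], k: int,
                       label: str | None = None) -> GeneSet:
    """All genes in the k most-constrained deciles (decile > 10 - k)."""
    if not 1 <= k <= N_DECILES:
        raise ValueError(f"k must be in 1..{N_DECILES}, got {k}")
    members = frozenset(e.gene for e in entries if e.decile > N_DECILES - k)
    return GeneSet(label or f"top_{k}_deciles", members)


def decile_burden_test(entries: list[ConstraintEntry], flagged: GeneSet) -> BurdenResult:
    """Per-decile flagged fractions plus ANOVA and trend statistics.

    The ANOVA treats the 0/1 flag as the response and decile as the
    grouping factor.  Because a binary response makes ANOVA somewhat
    unconventional, a chi-square test for linear trend in proportions
    (Cochran-Armitage with decile number as the score) is reported
    alongside; neither replaces the other.  When no flagged gene
    intersects the table both statistics are NaN.
    """
    flags = {e.gene: (1 if e.gene in flagged else 0) for e in entries}
    rows = []
    groups = []
    for d in range(1, N_DECILES + 1):
        vals = np.array([flags[e.gene] for e in entries if e.decile == d], dtype=float)
        groups.append(vals)
        rows.append({
            "decile": d,
            "n_genes": int(len(vals)),
            "n_flagged": int(vals.sum()) if len(vals) else 0,
            "fraction_flagged": float(vals.mean()) if len(vals) else 0.0,
        })
    per_decile = pd.DataFrame(rows)
    total_flagged = int(per_decile["n_flagged"].sum())

    if total_flagged == 0:
        nan = float("nan")
        return BurdenResult(per_decile, nan, nan, nan, nan)

    nonempty = [g for g in groups if len(g)]
    with np.errstate(invalid="ignore", divide="ignore"):
        anova = stats.f_oneway(*nonempty)
    anova_F = float(anova.statistic)
    anova_p = float(anova.pvalue)
    if math.isnan(anova_F):  # degenerate grouping (e.g., constant response)
        anova_p = float("nan")

    # Cochran-Armitage trend: score each decile by its number
    n_d = per_decile["n_genes"].to_numpy(dtype=float)
    k_d = per_decile["n_flagged"].to_numpy(dtype=float)
    t = per_decile["decile"].to_numpy(dtype=float)
    N = n_d.sum()
    pbar = k_d.sum() / N
    T = float((t * k_d).sum())
    e_T = pbar * float((t * n_d).sum())
    var_T = pbar * (1 - pbar) * (float((n_d * t**2).sum()) - float((n_d * t).sum())**2 / N)
    if var_T <= 0:
        trend_chi2, trend_p = float("nan"), float("nan")
    else:
        trend_chi2 = (T - e_T) ** 2 / var_T
        trend_p = float(stats.chi2.sf(trend_chi2, df=1))
    return BurdenResult(per_decile, anova_F, anova_p, trend_chi2, trend_p)
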