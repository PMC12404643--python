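# Methods

## The prioritization model

The pipeline operationalizes a simple generative premise: genes whose
haploinsufficiency causes congenital heart defects are (i) under
strong selective constraint in the adult population — high *s*het, the
per-gene heterozygote selection coefficient estimated from the
depletion of protein-truncating variants — and (ii) expressed in the
embryonic cardiac muscle cell lineage, and (iii) their protein
products form a functionally coherent neighborhood in the interaction
network together with already-established disease genes. Candidates
are therefore the intersection of the top *s*het deciles with the
cardiac-expression union; their plausibility is assessed by network
edge enrichment, cluster composition and term over-representation
rather than by any per-gene classifier. All gene identity is at the
approved-symbol level (case-insensitive matching, alias/previous
symbols resolved through a catalog snapshot); proteins map 1:1 to gene
symbols with no isoform expansion.

## Decile binning and the burden test

Genes are sorted ascending by *s*het with ties broken by symbol, then
cut into 10 contiguous bins; with *n* = 10*q* + *r* genes the *r*
remainder genes pad the lowest deciles, so decile 10 (most
constrained) always holds exactly *q* genes. The orientation
(10 = most constrained) is a package convention; published constraint
tables that ship their own decile labels can override via a `decile`
column, since their orientation is not always documented.

The burden test reports two statistics on the binary flag (gene is /
is not in the flagged list) grouped by decile:

* one-way ANOVA *F* and *p* (scipy `f_oneway` on the 0/1 response) —
  the conventional presentation for this analysis, retained even
  though ANOVA on binary data is unconventional;
* a Cochran–Armitage-style χ² for linear trend in proportions with
  decile number as the score,
  χ² = (T − E[T])² / Var(T), T = Σ t_d k_d, computed directly from its
  closed form (no installed package exposes this score-based test as a
  single call) — a robustness companion, not a replacement.

When perfect separation makes the within-group variance zero the
ANOVA *F* is infinite and *p* = 0; this is a legitimate extreme
outcome, not an error. The NaN "undefined" marker is reserved for
genuinely degenerate input (no flagged gene intersects the table).

## Overlap and term statistics

Set overlaps use the upper-tail hypergeometric probability
P(K ≥ k) with the scored-gene table as the default universe. Term
over-representation uses the same tail with parameters (N, K, n)
restricted to the chosen universe; only terms with at least
`min_hits` (default 2) query hits are tested, and Bonferroni
multiplies by that tested count — correcting over untestable terms
would be needlessly conservative and does not match how annotation
servers behave. An EASE mode (upper tail at k − 1) is available for
users who want the jackknifed, more conservative variant. Annotations
are flat: no ontology-graph ancestor propagation.

## Network construction and the permutation enrichment P

Edge tables use the STRING `protein.links` flat dialect; combined
scores in the 0–1000 integer dialect are divided by 1000, and the
confidence threshold is inclusive (score ≥ 0.7 by default, matching
the "minimum required interaction score" semantics). Symmetric
duplicate rows collapse to the maximum reported confidence; self-loops
are dropped with a warning. The induced network over a query keeps
exactly the stored edges with both endpoints in the query; with
`hide_disconnected` (the default, matching standard network-viewer
settings) zero-degree nodes are removed.

The edge-enrichment *P* is a Monte-Carlo analogue of the analytic
value reported by network databases (whose exact null is not public):
each permutation draws |nodes| proteins uniformly without replacement
from the background protein universe and counts induced background
edges at the same threshold;
*P* = (1 + #{null ≥ observed}) / (n_perm + 1), bounded below by
1/(n_perm + 1) and bit-reproducible given the seed. The null is
degree-naive by default; a degree-binned sampling mode (stratified by
background-degree decile) is provided for sensitivity analysis, since
uniform sampling is anti-conservative for high-degree query sets.

Calibration note: the permutation *P* is exactly super-uniform under
exchangeability, but its observable distribution is as fine-grained as
the induced-edge-count statistic. The calibration test therefore uses
a background dense enough (ER *p* = 0.15, 20-node queries) that the
count spreads over many values; on very sparse backgrounds the
*P*-value is tie-heavy and visibly conservative, which is the expected
behavior, not a defect.

## Cluster scoring and subnetwork extraction

Clusters are inputs (precomputed functional groups); no graph
clustering is performed. Each cluster is restricted to members present
as network nodes and scored by novel-candidate richness, where
"novel" means category `candidate_only` — candidates that are *not*
known disease genes, the genes whose implication is the new
information. Ranking is lexicographic (fraction novel, then novel
count, then cluster id); fraction-first was chosen because a small
all-novel cluster is a sharper lead than a large mixed one, and the
count-second key breaks fraction ties in favor of the larger signal.
The returned scores carry both keys so the count-first alternative is
a re-sort away. The subnetwork around a seed set is the induced
subgraph on seeds ∪ first neighbors — neighbor–neighbor edges are
retained, exactly what one gets by re-entering that gene list into a
network builder with no shell expansion.

## Cardiac measurement formulas

Heart rate = (5 / t) × 60 bpm where t spans five cardiac cycles.
Fractional area change (FAC) = (A_diastole − A_systole)/A_diastole
× 100; it is computed per replicate cycle and then averaged per
animal, with the FAC of the averaged areas emitted alongside since the
two differ under beat-to-beat variability. Relative expression uses
ΔCt = Ct_target − Ct_reference, ΔΔCt = ΔCt − mean(control ΔCt), and
fold = 2^(−ΔΔCt); the raw ΔΔCt column is always emitted because the
fold transform is a convention, not information. By construction the
geometric mean of control fold changes is exactly 1. Negative FAC
(systolic area above diastolic) is flagged but returned — it almost
always means swapped frames, which the analyst should see, not an
exception.

## Synthetic study conditions

The generator's defaults are the package's study conditions, fixed
once:

| parameter | default | rationale |
|---|---|---|
| n_genes | 2000 | desk-scale genome: large enough for stable deciles and a sparse network, seconds per bundle |
| constraint mixture | 0.2 · Beta(4, 6) + 0.8 · Beta(0.5, 10) | heavy right tail: most genes weakly constrained, a constrained minority, as in empirical *s*het tables |
| n_module | 40 | planted disease-module size |
| p_module_high_constraint, p_module_expressed | 0.9, 0.9 | module genes nearly always pass both filters, so candidate recall is informative |
| n_known / fraction in module | 60 / 0.4 | known genes partly inside the module, as known disease genes are |
| expression set size | 300 | filter keeps ~15% of the genome |
| DNV base rate / module enrichment | 0.02 / 8× | cases carry an excess of module hits; controls are flat |
| SBM edge probabilities | 0.35 within module, 0.003 background | dense functional neighborhood in a sparse interactome |
| fraction of edges ≥ 0.7 | 0.9 | most reported interactions survive the high-confidence cutoff |
| clusters | 12 total; planted size 10, novel fraction 0.8; background ≤ 0.3 | one novel-rich cluster among mostly-known background clusters |
| terms | 40; 3 planted at 60% module membership | planted terms rank first in candidate enrichment |

Module genes forced to be constrained are placed uniformly above the
empirical top-two-decile boundary of the background scores; the tiny
shift the replacement itself causes is negligible at 40/2000. Cluster
annotations list network-node members (the shape cluster tables
exported from network tools actually have), sampled with exact
novel/known composition, so planted-versus-background ordering is a
property of the scoring rule rather than of sampling noise. All
randomness flows from one integer seed through named `SeedSequence`
sub-streams; bundles are bit-identical per seed, and a SHA-256
fingerprint over the rendered files guards truth/output pairings.

What the generator does **not** emulate: the empirical *s*het
distribution's published parameters, scale-free degree structure
(the SBM background is Poisson-degree), annotation redundancy between
overlapping GO terms, and symbol-level noise (aliases, withdrawn
symbols) beyond what the catalog tests cover. Passing recovery tests
therefore demonstrates correctness of the machinery under a known
generative model, not performance on real databases.

## Pipeline orchestration

Stages run in dependency order; each optional input that is missing
downgrades its stage to `SKIPPED` so the set-algebra core remains
runnable from the gene tables alone. A failing stage aborts the run
with the stage name, retains partial outputs and records a `FAILED`
marker in the manifest. The manifest stores parameters, input
SHA-256 checksums, per-stage status and headline numbers; identical
inputs and seed reproduce byte-identical outputs. Integration checks
against third-party supplement files (candidate ∩ case-DNV genes,
published count 44; candidate ∩ human embryonic-heart-expressed
genes, published count 154) report REPRODUCED/MISMATCH when those
files are supplied and SKIPPED otherwise; the files are not
redistributable and are never bundled.

## Problem sizes in the test and acceptance runs

Unit and property tests run on toys (≤ tens of genes) or single
2000-gene bundles; calibration tests use 500 burden simulations, 60
null-bundle seeds and 200 permutation-test queries; the recovery sweep
uses 50 seeds of the default condition. The acceptance script runs
one full pipeline at n_perm = 999 plus the 50-seed sweep. These sizes
were chosen so the whole suite completes in well under a minute while
keeping every Monte-Carlo check statistically meaningful.

## Known limitations

* ANOVA on a binary response is reported because it is the
  conventional presentation for decile burden; the trend χ² is the
  statistically appropriate companion and both are always emitted.
* The permutation enrichment null ignores degree structure by
  default; for hub-heavy query sets use the degree-binned mode.
* Ortholog mapping retains all one-to-many targets (union); any
  conflict resolution policy beyond that must happen upstream.
* Cluster scoring depends on the category assignment; genes pulled
  into a subnetwork only as neighbors are never counted as novel.
* The synthetic benchmark is a planted-model sanity harness, not a
  calibration against any real interactome or constraint table.
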