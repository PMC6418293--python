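# Methods

## Knowledge graph

Entities carry one of five types — gene, disease, phenotype, pathway, taxon
— encoded in a namespaced id (`gene:VPS4A`; the namespace is the text before
the first colon, so compound local ids like `gene:hsa:G1` are legal).  The
link-type registry is fixed: `gene_disease`, `gene_phenotype`,
`gene_pathway`, `gene_orthologue` (gene↔gene, strictly cross-taxon) and
`gene_taxon`.  All links are undirected associations; direction exists only
in metapath traversal order.  Duplicate `(source, target, link_type)`
triples collapse to the maximum weight, which makes re-loading a file
idempotent.  A gene's taxon annotation automatically materializes its
`gene_taxon` edge, so the on-disk dialect (entities.tsv + per-link-type
TSV/GMT files) round-trips the graph exactly.

Edge weights default to 1.0.  Association scores (e.g. curated
gene–disease confidence values) can be loaded into the weight field, but
propagation ignores weights unless explicitly enabled: ranked relevance
output gives no reason to presume score weighting, so unweighted instance
counting is the default and weighting is a flag.

## Metapath evidence propagation

A metapath is an ordered list of steps, each a link type with an optional
`reverse` flag and an optional taxon filter on gene-typed step targets.
Three models are built in:

| model | steps | reading |
|---|---|---|
| `model_1` | gene→disease | direct literature associations |
| `model_2` | gene→pathway, pathway→gene, gene→disease | pathway co-membership |
| `model_3` | gene→orthologue(bridge), gene→pathway, pathway→gene, gene→orthologue(seed taxon), gene→disease | orthologue pathway co-membership in another species |

(`disease` is interchangeable with `phenotype`.)  The raw score of target
*t* is the sum over all metapath instances — distinct edge sequences
following the step types — of the product of step contributions.  This is
computed as the seed indicator row vector pushed through the chain of
per-step sparse adjacency matrices; a brute-force depth-first enumeration
oracle in the test suite pins the semantics on hundreds of random graphs.
Two propagation options exist: `use_edge_weights` multiplies each step by
the edge weight, and `step_normalization="per_source_degree"` divides each
step's contribution by the source node's degree under that link type
(degree-0 sources contribute 0).  In `model_3` the returning orthologue
step is filtered to the seed set's taxon, so paths re-entering the bridge
taxon are not followed; because orthologue edges are strictly cross-taxon,
this keeps the five-step path finite and acyclic across steps.

Scores are max-normalized per run to [0, 1]; an all-zero score vector is
returned unchanged and flagged in the run metadata.  Ranks are descending
raw score with lexicographic target-id tie-break, and reports truncate to
the top 20 targets by default (`top_k`, `full_table` override).

## Permutation test

For each target, `p = (1 + #{permutations with score ≥ observed}) /
(1 + n_perm)` — the add-one estimator, so p is never 0 and lies on the grid
`[1/(n_perm+1), 1]`.  The null universe is every gene of the seed's taxon
present in the graph (an unconditional null); a flag restricts it to genes
carrying at least one first-step edge.  Permuted sets match the size of the
*retained* seed (seed genes absent from the graph are dropped with a
warning), keeping observed and null scores comparable.  `n_perm` defaults
to 999 (p granularity 0.001).  All draws come from one integer-seeded
generator consumed in a fixed order (a single uniform matrix per run, rows
= permutations), so results are platform-independent; permuted indicator
rows are pushed through the matrix chain as one sparse block, which is what
keeps 999 permutations effectively free.

A seed set at least as large as its null universe admits no non-trivial
permutation and is rejected as a configuration error.

## Ensemble enrichment

The gene-level statistic is a per-gene Welch t (second group minus first;
rows with missing values dropped with a warning; zero-variance identical
groups give t = 0).  Precomputed statistics from any external
differential-expression fit can be supplied instead — the ensemble only
sees a named vector over a gene universe.  Three algorithm families cover
overlap, rank and running-sum evidence:

- **ORA** — the top `ora_selection` (default 5%) of the universe by
  |statistic| (ties broken by gene id) is tested for overlap with the set
  by the hypergeometric upper tail P(X ≥ k).
- **rank-sum** — two-sided Wilcoxon rank-sum of |statistic|, members vs
  non-members; exact null for universes ≤ 50 genes, normal approximation
  with tie correction above.
- **KS permutation** — universe sorted by signed statistic descending;
  running sum adds the member's |statistic| (normalized; weight exponent 1)
  at hits and subtracts 1/(N−K) at misses; ES is the extremum of larger
  magnitude (ties resolve positive).  The null permutes member labels:
  exhaustively over all C(N, K) placements when that count does not exceed
  `ks_n_perm` (the p-value is then exact), otherwise `ks_n_perm` sampled
  placements with the add-one estimator, two-sided on |ES|.  Only hit
  positions are inspected when evaluating ES (the running sum rises exactly
  at hits and its local minima sit immediately before them), which
  vectorizes the permutation null.

Per-pair p-values combine by Fisher's method (default; χ² = −2Σln p on 2m
df), Stouffer's equal-weight z, or Wilkinson's median order-statistic (Beta
tail of the ⌈m/2⌉-th smallest p).  Combined p-values are BH-adjusted across
gene sets within each contrast (per-contrast rows are the reporting unit; a
global-adjust flag exists) and flagged enriched at adjusted p < 0.05.  The
KS permutation stream is re-seeded per gene-set index, so duplicated
contrasts yield identical rows.

The three-algorithm roster is a deliberate desk-scale ensemble: one
algorithm per evidence family preserves the ensemble character while every
component remains individually verifiable against closed forms or
exhaustive enumeration.  The roster is configurable so further algorithms
can be added.

## Synthetic data

The graph generator draws, per link type, independent Bernoulli background
edges (defaults: gene–disease and gene–phenotype 0.01, gene–pathway 0.05)
over per-taxon gene universes (two taxa × 200 genes; 100 diseases, 50
phenotypes, 20 pathways per taxon), plus one-to-one orthologue wiring
covering 80% of seed-taxon genes.  Planted blocks wire a disease to a
random 10-gene seed set directly, through a dedicated pathway (its extra
members carry the disease links, so only `model_2` sees the signal), or
through orthologue-pathway wiring in a bridge taxon (only `model_3`).
Planted diseases participate in background drawing like any other disease.
Erdős–Rényi backgrounds rather than degree-matched rewiring are a
deliberate simplification: the simplest null sufficient for calibration;
degree-preserving nulls are future work.  One-to-one orthologue wiring
avoids combinatorial path inflation in the five-step model.

The expression generator emulates a two-group experiment: i.i.d.
Gaussian(0, 1) noise over 1000 genes × (10+10) samples, one planted 50-gene
set with half its members shifted by δ = 1 SD in the second group, and four
size-matched unshifted decoy sets, drawn disjointly while genes remain.
Four decoys alongside one planted set mirror a five-gene-set screening
layout while giving a pooled decoy pool for false-positive-rate checks.

What the generators do **not** emulate: real association databases'
heavy-tailed degree distributions, realistic pathway size distributions,
probe-level microarray artifacts, correlated expression noise, or
heteroscedasticity.  Passing tests therefore demonstrate correctness of
the statistical machinery and recoverability of signals of the stated
magnitude — not performance on any particular real resource.

## Calibration checks

Permutation p-values are checked for uniformity on a null (unplanted)
graph.  With unit edge weights, raw scores are small path counts; heavy
ties make the add-one p-value super-uniform by construction, so strict
grid-uniformity is only observable in the tie-free regime.  The
calibration runs therefore draw continuous Uniform(0.5, 1.5) gene–disease
weights (`gene_disease_weight="uniform"`) and propagate with weights
enabled, on a dense single-taxon graph (60 genes × 20 diseases, density
0.5) where a fixed target's score is almost surely positive.  Under this
design the p-value of a fixed target is uniform on the grid
`{1/(n+1), …, 1}` and a KS goodness-of-fit test across replicate graphs
applies directly.

ORA, being a discrete test, has super-uniform (conservative) null
p-values — its null CDF steps touch the diagonal only at achievable
points — so it is checked for P(p ≤ t) ≤ t rather than strict uniformity;
the rank-sum (asymptotic, continuous statistics) and KS-permutation
(continuous ES grid) nulls are checked by KS goodness of fit.

## Numerical and determinism notes

- Score comparisons in permutation counting use a 10⁻⁹ relative tolerance
  so float products of weighted steps cannot flip a tie; with unit weights
  scores are exact integers.
- Entity orderings are sorted everywhere matrices or reports are built;
  ranks break ties lexicographically; every rng is integer-seeded.  Reports
  rerun with the same configuration and seed are byte-identical (the run
  log, which timestamps events, is the one deliberately non-reproducible
  artifact).
- Welch t of a zero-variance, zero-difference gene is defined as 0;
  non-finite t values are clipped to ±10¹⁵.
- All-zero KS member weights (every member statistic exactly 0) fall back
  to uniform hit increments.
- Report precision: wide tables print two decimals (relevance and p), the
  long-format companions print full precision (`%.10g`).

## Problem sizes used in the shipped checks

Oracle equivalence runs 200 random graphs of ≤ 60 entities; null
calibration 200 replicate graphs at 199 permutations; planted-association
recovery and ensemble power 100 generator seeds each at the default
scenario sizes; exhaustive enumeration oracles run on universes of 10–12
genes.  These sizes give binomial/KS margins comfortably inside the
asserted thresholds while keeping the full suite in tens of seconds.

## Known limitations

- The propagation semantics (metapath-instance counting) is the simplest
  scheme consistent with evidence flowing along typed links; alternatives
  (random-walk with restart, degree-corrected propagation) are only
  partially covered by the `per_source_degree` option.
- No multiple-testing correction across diseases in the prioritization
  stage (raw permutation p-values are reported, as in per-column relevance
  tables); the enrichment stage's BH scope is per contrast.
- The ensemble is a three-algorithm stand-in for larger published
  ensembles; it preserves the combination-and-adjust architecture, not any
  specific roster.
- Orthologue wiring is one-to-one; paralog fan-out is not modeled.
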