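# Methods

## Model overview

The package compares two biological conditions (generically A and B, with
one designated "positive", e.g. a disease state) through *co-expressed
protein interaction networks* (CePINs). The inputs are a static protein
interaction network (PIN), a genes-by-samples expression matrix, a
two-condition sample design, and a Gene Ontology DAG with gene
annotations.

**Edge scoring.** For each PIN edge (X, Y) and condition c, the Pearson
correlation of the two genes' expression over condition-c samples is

    PCC(X,Y) = 1/(n−1) · Σ_i [(x_i − x̄)/s_x] · [(y_i − ȳ)/s_y],

with sample standard deviations and n the condition's sample count.
Significance is the two-sided p-value of the t transform
t = r·√(n−2)/√(1−r²) on n−2 degrees of freedom. Edges with p ≤ α
(default 0.05, inclusive) are co-expressed protein–protein interactions
(CePPIs); they form the condition's CePIN. Missing values are handled
pairwise-complete; an edge needs ≥ 3 complete pairs and non-constant
vectors, otherwise its score is undefined and it is never retained.

**Topology.** Degree, betweenness centrality (fractional shortest-path
counting normalized by C(N,2)), closeness centrality (reciprocal mean
shortest-path length), and the local clustering coefficient. Betweenness
and closeness are computed within the largest connected component only;
nodes outside it carry NaN. Differential expression is called per gene
by a two-sided Wilcoxon rank-sum test between conditions (exact by full
enumeration when C(n₁+n₂, n₁) ≤ 10⁶, otherwise the normal approximation
with midrank tie correction and no continuity correction). Hubs are
CePIN nodes whose degree strictly exceeds the (100−p)-th degree
percentile (default p = 1, linear interpolation between order
statistics) — strictness means an all-equal degree distribution has no
hubs.

**Two-stage enrichment.** Let the background be the annotated genes
present in both the expression data and the PIN (size N). For each
functional category, the gene-level test draws the category's n
background genes against the CePIN's m genes and asks for the upper
tail P(X ≥ k) of the hypergeometric distribution at the observed
overlap k. The dyad-level test repeats this at the edge level: a
*functional dyad* is an edge whose endpoints share the category; with
Ne background PIN edges, me CePPIs, ne category dyads in the background
and ke among CePPIs, the p-value is the hypergeometric upper tail of
(Ne, me, ne, ke). Both computations are exact, in log space (log-gamma),
so small-population oracle equality holds to 1e-12. Each family is
adjusted separately with the Benjamini–Hochberg step-up procedure.

**Module discovery.** A category is a *candidate* in a condition when
both its adjusted p-values are ≤ α (default 0.05). Exclusive categories
are the set difference of the two candidate sets (both directions are
always computed). A minimum ontology level (default 5; root = level 1,
level(t) = 1 + min over parents, i.e. shortest path) removes overly
generic categories after the difference. Each survivor becomes a module:
its annotated genes among the CePIN nodes plus the CePPIs joining them.

**Evaluation.** (1) Classification: samples are clustered (average-
linkage UPGMA on Euclidean distance by default; single/complete/ward
configurable) on the module's gene expression; the dendrogram is cut at
the root; the branch with more positive-condition samples is the
predicted positive class (an exact tie goes to the branch containing
the lexicographically smallest sample id, and is flagged). Sensitivity
= TP/(TP+FN), specificity = TN/(FP+TN), accuracy = (TP+TN)/N. The
per-sample module activity score (mean expression over member genes)
yields a ROC curve; AUC equals the Mann–Whitney pairwise concordance
with half-credit for ties, with orientation auto-selected so AUC ≥ 0.5.
(2) Dynamics: three observed statistics — mean pairwise within-condition
PCC of member genes (per condition), mean absolute per-gene condition-
mean difference, and mean |PCC_A − PCC_B| over member CePPIs — are each
compared against random gene sets of equal size drawn uniformly from
the measured genes, giving Z = (obs − null mean)/null sd and an add-one
empirical p = (1 + #{null ≥ obs})/(1 + n_null). (3) Edge rewiring:
each scored edge is classed as A-specific / B-specific / both / neither
by |PCC| ≥ 0.5 (configurable) per condition.

**Re-sampling robustness.** For each subsample size, samples are drawn
without replacement within each condition, and the CePIN construction
and module discovery are re-run; the CePPI recovery rate (fraction of
full-data CePPIs recovered) and per-category identification rate are
reported per size.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha_edge` | 0.05 | edge-significance cut (inclusive) for CePPIs |
| `alpha_sdeg` | 0.05 | rank-sum cut for differential expression |
| `alpha_enrich` | 0.05 | BH-adjusted cut for both enrichment families |
| `min_go_level` | 5 | minimum ontology depth of a module's category |
| `hub_percentile` | 1 | top percentile of the CePIN degree distribution |
| `edge_dyn_threshold` | 0.5 | \|PCC\| cut for edge-rewiring classes |
| `n_null` | 1000 | random gene sets per dynamics null |
| `linkage` | average | hierarchical-clustering linkage |

All thresholds are on probability or correlation scales (unitless);
expression values are used as provided (log scale assumed).

## The synthetic generator

`simulate.SyntheticSpec` defines the study conditions: 300 genes, 800
interactions, 15 + 15 samples, and two planted categories of 20 genes
at ontology level 6 — one exclusive to condition A (target
within-condition pairwise correlation ρ_A = 0.8 vs ρ_B = 0, members
mean-shifted by `sdeg_shift` = 1.0 in A) and one co-expressed in both
conditions (ρ = 0.8 / 0.8, no shift). Member genes follow a one-factor
Gaussian model x_g = √ρ·f_sample + √(1−ρ)·σ·ε, so ρ is directly the
expected pairwise correlation; background genes are i.i.d. standard
normal and are annotated to decoy categories of matched size (plus two
level-3 decoys that exercise the level filter). The PIN is a uniform
random graph over a global spanning tree, with each planted category's
members pre-wired into a connected subgraph. Everything is a pure
function of the spec (seed included): bundles are byte-identical across
regenerations.

Two derived fixtures: `null_spec` (no planted structure; used for
type-I and Z-calibration checks) and `activity_shift_spec` (a 20-gene
module whose genes gain δ = 1.5 in the positive condition with no
shared factor; used for classification power, since the activity shift
is the quantity classification is meant to detect — a strong shared
factor would add sample-level activity variance unrelated to class).

What the generator does *not* emulate: microarray probe-level noise and
normalization artifacts, the scale-free degree structure and annotation
depth heterogeneity of real interactomes and GO, and correlated
background co-expression. Passing tests therefore demonstrate the
statistical machinery's correctness and calibration under the assumed
model, not performance on any particular cohort.

## Numerical choices and degenerate inputs

- Correlations are clipped to [−1, 1]; |r| = 1 reports p = 0 with a
  degeneracy flag; constant vectors yield an undefined (excluded) score
  rather than an exception.
- The hypergeometric tail and BH adjustment are exact (log-gamma sums,
  step-up with a running minimum); Fisher's two-sided p sums all tables
  with mass ≤ observed × (1 + 1e−7), the standard convention.
- Component-size ties in the largest-connected-component rule break to
  the component containing the lexicographically smallest node.
- A category with no background dyad gets p = 1 with a flag; a module
  whose members share no CePPI is flagged, not an error; the dynamics
  ΔPCC null statistic runs over all pairs of the drawn gene set (random
  gene sets carry no edges of their own; a connected-subgraph sampler is
  available as `mode="connected"`).
- All pipeline outputs are sorted and written with fixed float formats;
  identical configurations produce byte-identical result bundles.

## Scales used by the test suite and acceptance script

The shipped checks run at desk scale, chosen as the package's reference
conditions: exhaustive hypergeometric verification to N ≤ 25; 100
random graphs (≤ 40 nodes) against brute-force topology oracles; 20
seeds for planted-module recovery, classification power and planted-Z
checks; 200 seeds for type-I control and null-Z calibration; 20 seeds ×
3 repeats for re-sampling curves. `scripts/acceptance.py` recomputes
the same quantities at 10–50 seeds per quantity.

## Known limitations

- The dyad test treats edges as exchangeable draws, ignoring that edges
  sharing a node are dependent; this mirrors the method's own
  assumption and can be anti-conservative for categories concentrated
  on hubs.
- Exact Wilcoxon enumeration is quadratic-exponential in group sizes
  and is only used below the 10⁶-combination threshold; above it the
  tie-corrected normal approximation applies.
- Identifier mapping (probes to genes, proteins to genes) is a plain
  two-column relabel hook; no web-service lookups.
- The classifier is the root split of a dendrogram, faithful to the
  evaluation it reproduces but far from a tuned classifier; AUC from
  the activity score is the more stable metric on small cohorts.
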