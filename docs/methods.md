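# Methods

This note documents the statistical and algorithmic choices behind
`crosstalk`, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Differential calling

Intensities are modelled on the log2 scale. For each protein the fold
change is the geometric-mean ratio `2^(mean(log2 case) − mean(log2
control))`, consistent with testing log2 signals, and the p-value comes
from a two-sided two-sample Student *t*-test with pooled variance (Welch
is available via `welch=True`; the pooled test is the default because the
classical equal-variance test is the stated analysis of the emulated study
design, three technical replicates of a pooled sample per group). A
protein is a DEP when FC ≥ `fc_up` (default 1.2) **or** FC ≤ `fc_down`
(default 0.83), both inclusive, and raw *p* < `alpha` (default 0.05). No
multiple-testing correction is applied at this stage; FDR control enters
only in pathway enrichment.

Degenerate rows are handled explicitly: when both groups are constant
(per-group range exactly 0 — variance can round to a subnormal for
identical floats, so range is the robust test) and the group means agree,
the test is undefined and the record is flagged `untestable`, never DEP;
constant but separated groups are infinitely significant (*p* = 0).

`differential_rate_test` compares DEP rates inside vs outside a partition
(secreted vs non-secreted) with the Pearson chi-square on the induced 2×2
table, df = 1, without continuity correction:
`N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d))`.

## Core networks

The **seed net** of a tissue is the background subgraph induced by its
DEPs plus their direct neighbors, direction ignored. Each connected
component containing at least one seed is reduced to a Steiner tree over
that component's seeds with unit edge weights; a single-seed component
contributes the bare seed node; seed-free components are dropped. The
union of trees is the core network, so the result is always a forest.

The approximation is the metric-closure construction (terminal distance
graph → MST → path expansion → non-terminal leaf pruning), which is a
2-approximation of the optimum; components are relabelled
lexicographically before solving so shortest-path and MST tie-breaks are
deterministic. An exact solver (exhaustive connector-subset search) is
available behind `exact_small=True` for components of ≤ 12 nodes; it is
also the independent oracle in the test suite. Verified bounds: the tree
is within 2× the brute-force optimum on every labeled connected graph
with ≤ 5 nodes (exhaustive, all terminal subsets of 2–4) and on a seeded
sample of connected 6–9-node graphs; two-terminal instances reduce
exactly to shortest paths; a tree whose nodes are all terminals is
returned unchanged. Exhausting all labeled graphs beyond 5 nodes is
combinatorially pointless (millions of isomorphic copies), hence the
sampled extension.

**Density** is `2E/(N(N−1))` over nodes of degree ≥ 1. The edge-based
variant `E/(E(E−1)/2)` is retained behind `literal_density=True` for
auditability, but it is not a density (its denominator does not count
potential edges) and is never used by the pipeline.

**Null-model validation** resamples `n_seeds` background nodes uniformly
without replacement (not degree-matched — a degree-stratified null is a
possible extension but is not the stated procedure), reruns the *full*
construction (seed net + Steiner + stats; only rerunning the seed net
would make the three metrics incomparable), and reports
`z = (observed − null mean)/null sd` with the sample sd (ddof = 1) per
metric over `n_null` draws (default 100). The network passes when
|z| > `z_threshold` (default 2.33, the two-sided 1% point) on all of
connected nodes, edges and density; a metric with null sd 0 yields an
undefined z and an automatic fail with a stated reason. Everything is
reproducible from `rng_seed`.

## Cross-tissue interface

Ligands of tissue A are its secreted DEPs surviving the low-expression
filter: a protein is excluded from A when its atlas expression in **some**
other tissue exceeds `fold` (default 10) × its expression in A. The
"more than 10 times lower than any other tissue" rule is read with the
maximum over other tissues as the witness — the most conservative reading
against false cross-tissue signal. Missing atlas values exempt a protein
(unknown ≠ low, otherwise atlas gaps would silently delete ligands); the
comparison runs over whatever tissues the atlas contains.

A cross edge A→B is emitted for every directed background edge
ligand → r with r non-secreted and present in B's core network. Receptors
are *not* required to be differential by default; the stricter reading is
available via `receptor_dep=True`. Same-tissue (autocrine) edges are
excluded by construction. Upstream pairs (regulator DEP → ligand) are
kept only for ligands that actually emit ≥ 1 cross edge — the interface
is defined around realized inter-tissue connections — while downstream
pairs (receptor → effector DEP, within the receptor's tissue) are
computed for every receptor. Every built interface is checked against its
structural invariants (direction, secretion status, background support)
before being returned.

## Enrichment and functional quantification

Over-representation uses the exact hypergeometric upper tail
`P(X ≥ k)` with Benjamini–Hochberg FDR across the tested pathways.
Excluded pathways (disease maps, global maps) are dropped before testing
and never count toward protein classification or the background
proportion. The enrichment background defaults to the tissue's detected
proteins intersected with the pathway universe — proteomics detection
defines the sampling frame — and is caller-configurable to any other
universe. Pathways with no background members are skipped, not scored;
result ranking breaks ties by (fdr, p, pathway id) so top-k selections
are reproducible.

Protein roles: *metabolic enzyme* = has an EC number and every
(non-excluded) pathway containing it is metabolic, with ≥ 1 such pathway;
*signaling protein* = in ≥ 1 signaling pathway and in no metabolic one;
everything else (including kinases mapping to both) is *other*. Edge
typing marks an edge metabolic-involved/signaling-involved if ≥ 1
endpoint has the role; mixed edges carry both labels by default, with a
precedence variant exposed because per-class percentages do not by
themselves fix an exclusivity convention.

Each (tissue, side) process set contributes one metabolic proportion —
the fraction of its FDR-significant pathways classed metabolic; sets with
empty enrichment are skipped and the effective n is reported rather than
assumed. The one-sample z-test compares the mean proportion to the basic
pathway universe's metabolic share: `z = (mean − p0)/(sd/√n)` with sample
sd, normal two-sided p, and a 95% CI of `mean ± 1.96·sd/√n`. It requires
n ≥ 2 and sd > 0; degenerate inputs raise rather than fabricate a
p-value. "Dominant" upstream category = plurality of enriched-pathway
subcategories (ties reported in full; a −log10 p-weighted variant is
available).

## Synthetic data

`FixtureSpec` defaults encode the emulated study conditions: 3 tissues,
3 replicates per group, planted linear fold change 2.0 with log2 noise
sd 0.1, a secretome of ~5% of proteins, and a metabolic pathway fraction
of 91/243. The background is directed Erdős–Rényi (mean out-degree 3,
fixed once; a preferential-attachment option exists because interactome
degree heterogeneity changes Steiner behaviour). Planted axes
(upstream → ligand → receptor → effector) are inserted by direct
construction; the generator never calls the analysis code, so recovery
tests are non-circular.

Three construction rules make planted-axis recovery a sharp property:
random secreted proteins are drawn from never-differential proteins (so
planted ligands are the only secreted DEPs), ligands emit no random
out-edges, and receptors carry no random edges at all (a receptor with
random edges can be retained as a Steiner connector in a third tissue's
network and absorb real-but-unplanted cross edges). Planted receptors are
made DEPs of their target tissue so they survive Steiner simplification
under both receptor modes. Atlas rows for ligands are high in the source
tissue and > 10× lower elsewhere, exercising the expression filter in
both directions.

What the generator does **not** emulate: peptide-level mass-spec
artifacts (missing values, batch effects, intensity-dependent variance),
correlated co-regulation, hub-biased differential expression, and
identifier mismatch between resources. Passing recovery tests therefore
demonstrates correctness of the pipeline's logic under its stated model,
not robustness to real proteomics noise.

## Problem sizes and numerical choices

The default test and acceptance workloads are sized for interactive runs:
synthetic bundles of 120–300 proteins, null models of 100 draws,
calibration over 20 seeds × 100 proteins, and the exhaustive Steiner and
hypergeometric grids described above (literal subset enumeration up to
N = 9, combinatorial-identity oracle to N = 12). All RNG flows through
`numpy.random.default_rng` seeded per operation from one spec/config
seed; no global RNG state is touched. Reports contain no timestamps, so
identical configs and seeds give byte-identical outputs.

## Limitations

* The Steiner 2-approximation can retain a connector the optimum avoids;
  only ≤ 12-node components can be solved exactly.
* The uniform null model ignores seed degree bias; dense, well-annotated
  hub neighbourhoods may inflate |Z| for real seed sets.
* Enrichment treats gene sets as flat collections; ontology structure
  (term nesting, DAG propagation) is out of scope.
* The interface is qualitative: it identifies regulatory routes, not
  ligand flux or binding affinity, and its direction comes entirely from
  the curated background network.
* On small inputs, process sets often have no FDR-significant pathways;
  the z-test is then reported as absent rather than computed on an
  unstable n.
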