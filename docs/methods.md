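# Methods

This note documents the models, algorithms and numerical choices behind
`spectral-supertree`, and what its synthetic benchmarks do and do not
establish.

## Trees and the proper cluster graph

A rooted (possibly multifurcating) tree carries unique leaf labels and,
optionally, branch lengths on every non-root node; partially annotated
trees are rejected at parse time. Taxon identity is the exact label
string — no case-folding or whitespace normalisation — because silent
renaming corrupts supertree leaf sets. Serialisation is canonical
(children ordered by smallest descendant leaf label), so every output is a
deterministic function of inputs and seed. Induced subtrees suppress
degree-2 chains and sum their branch lengths, preserving root-to-leaf path
lengths for the branch-length weighting. One- and two-leaf trees are
representable; they are the recursion's base-case outputs.

Two taxa form a proper cluster of a tree when their lowest common ancestor
is not the root. The proper cluster graph over the source trees has one
vertex per taxon and an edge per pair that is a proper cluster somewhere;
per-tree support is accumulated at the pair's exact LCA (pairs are
enumerated across child subtrees of each internal node, so each pair is
counted once per tree). Weighting strategies: `unit` adds the tree weight
`Wi`; `depth` adds `Wi` times the LCA's edge depth; `branch_length` adds
`Wi` times the LCA's branch-length distance from the root. Absent taxa
fall back to the root (depth and length 0), so they contribute nothing.
Under branch-length weighting an LCA at zero distance from the root yields
weight 0; such edges are dropped with a warning — zero weight is
indistinguishable from no support, and the normalized cut requires
positive weights.

## Contraction

Before partitioning, edges that no source tree could ever want cut are
contracted (transitively — connected components of the contraction-edge
subgraph merge; parallel edges keep the maximum weight). Two rules exist:

- spectral method: contract `(u, v)` when every source tree containing
  *either* taxon contains both and shows them as a proper cluster. A tree
  containing exactly one of the two blocks contraction. This is the
  stronger rule and fires often on mostly-agreeing inputs, collapsing the
  graph dramatically.
- min-cut baseline: contract only when *every* source tree shows the pair
  as a proper cluster (support equals the total tree weight). When depth
  or branch-length weights are requested, contraction eligibility is still
  decided on this unit-weight criterion while cut weights use the
  strategy, keeping the baseline faithful to its original definition.

Every edge satisfying the baseline rule satisfies the spectral rule
(tested); the converse fails.

## Partitioning

A disconnected (contracted) graph partitions the taxa by its components;
with k > 2 components the recursion branches k ways at once, which is how
root multifurcations arise. A connected graph is bipartitioned:

- spectral method: normalized-cut relaxation. `Ncut(A,B) =
  W(A,B)/W(A,V) + W(A,B)/W(B,V)` with the classical volume convention —
  `W(X,Y)` sums weights over ordered pairs, so within-block edges count
  twice and cut edges once. The embedding is the second-smallest
  generalized eigenvector of `(L, D)` (computed as `D^{-1/2} u2` from the
  symmetric normalized Laplacian; dense `eigh` up to 512 vertices,
  shift-invert Lanczos above), clustered by 2-means with 10 restarts and a
  seeded initialisation. If k-means degenerates to one cluster (possible
  with identical embedding values) the fallback splits at the median
  embedding value with ties broken by canonical vertex order, so the
  recursion always strictly shrinks. Vertices are groups of taxa after
  contraction; the affinity is over groups with unit masses (no
  size-reweighting).
- min-cut baseline: remove min-cut edges and take components. In
  `all_mincuts` mode an edge `e` is removed iff
  `mincut(G − e) = mincut(G) − w(e)` (the per-edge membership test);
  `single_mincut` removes one deterministic Stoer–Wagner minimum cut's
  crossing edges. Removal always disconnects the graph.

Both recursions share the same skeleton, run iteratively with an explicit
work stack (no interpreter recursion limits at 10,000+ taxa), and both
return a single remaining source tree unchanged when it spans the whole
subproblem. Source trees reduced to a single leaf are dropped from a
child's tree list, but the taxon stays in the child's taxon set and
surfaces as an isolated graph vertex, so no taxon is ever lost.

Seeding: one master seed per run; each recursion branch derives a child
`SeedSequence`, so runs are byte-reproducible and branches decorrelated.
All randomness sits in the k-means restarts — the rest of the pipeline is
deterministic by canonical ordering.

## Distance metrics

All three metrics operate on non-trivial clades (neither singletons nor
the full leaf set) and are defined only for equal leaf sets; comparing
trees on different taxa requires explicit induction first. Trivial clades
are shared whenever leaf sets agree, so they cancel in every symmetric
difference; excluding them also keeps the matching padding honest (an
empty set matched against a trivial clade would contribute spurious
weight).

- Robinson-Foulds: `|C(T1) ⊕ C(T2)| = FP + FN`.
- Rooted F1: `2TP/(2TP+FP+FN)`, defined as 1 when both trees are stars
  (identical empty clade sets). The identities `RF = 2TP(1/F1 − 1)` (TP >
  0) and, for fully resolved n-taxon trees, `RF = 2(n−2)(1−F1)` hold
  exactly in integer arithmetic and are asserted in the tests.
- Matching Cluster: minimum-weight perfect matching between clade lists,
  padded with empty sets to equal length; weights are computed vectorised
  (`|a|+|b|−2·a·b` over 0/1 incidence matrices) and the assignment is
  solved by the Hungarian algorithm (`scipy.optimize.linear_sum_assignment`).
  With weights replaced by 0/2 (match/mismatch) the matching total equals
  Robinson-Foulds on bifurcating same-size trees — asserted as a
  consistency check.

## Synthetic exact-recovery benchmarks

The generator emulates the merge stage of divide-and-conquer pipelines:

1. **Model tree**: constant-rate birth-death simulation (defaults: birth
   1.0, death 0.2 — both in units of events per lineage per unit time),
   conditioned on the requested number of extant tips, redrawing on
   extinction (delegated to dendropy's simulator). The ultrametric tree is
   rescaled to unit root-to-tip depth.
2. **Branch-rate evolution**: a scaling factor starts at 1.0 at the root
   and evolves towards the tips by Gaussian increments (sd 0.05 per node),
   clamped to [0.05, 8.0]; each node's factor multiplies its subtending
   branch. The factor evolves per node and applies to the branch above it.
3. **Decomposition**: recursive centroid-edge splitting until every part
   has at most `max_size` taxa. Each side keeps its own leaves plus a
   *short-subtree separator* from the opposite side: up to 4 leaves chosen
   nearest-first but spread round-robin across the distinct subtrees
   hanging off the centroid edge. Spreading matters: taking the overall
   nearest leaves can sample a single nearby branch, and the resulting
   source trees — though compatible and individually correct — then
   underdetermine the model tree near the boundary (both supertree methods
   return a different tree that still displays every source). With
   per-direction separators of width 4, exact recovery held in 50/50
   replicate instances across 50–500 taxa and subset caps 20/50. Both
   child subsets share the separators exchanged at their split, which
   makes the subset overlap graph connected by induction.
4. **Source trees**: the model tree induced on each subset — compatible by
   construction, and jointly resolving the model.

`perturb_tree` (random rooted NNI moves) provides graded conflict for
robustness tests. It is a deliberately simple stand-in for
maximum-likelihood estimation error: it does not model branch-length
error, long-branch attraction, or alignment noise, so passing the graded
degradation tests says nothing about behaviour under realistic estimation
error — only that conflict is handled and accuracy degrades smoothly
rather than collapsing.

What these benchmarks do not show: performance relative to other supertree
software on curated empirical collections, behaviour under systematically
biased (rather than random) conflict, and unrooted or partially rooted
inputs (out of scope throughout).

## Problem sizes and numerical choices

The test suite exercises exact recovery at 50–500 taxa (10 replicate seeds
per configuration, subset caps 20 and 50, both methods) and one
10,000-taxon instance with several hundred source trees for the spectral
method; these sizes were chosen to cover the regime where recursion depth,
contraction behaviour and the sparse eigensolver all engage while keeping
the suite quick on a laptop. The min-cut baseline's exact-recovery runs
use `single_mincut` mode — on compatible inputs the contracted graph is
essentially always disconnected, so the min-cut machinery is rarely
invoked and the two modes coincide; `all_mincuts` (quadratic in edges per
invocation) is exercised on small instances where its compatibility and
rooted-triple guarantees are asserted.

Ties everywhere (children order, component order, k-means degeneracy,
min-cut choice, brute-force Ncut oracle) break by lexicographic taxon or
canonical vertex order. Floating-point comparisons in the min-cut edge
test use a relative tolerance of 1e-9; clade arithmetic is exact (integer
set operations).

## Known limitations

- The spectral relaxation is not exact: on adversarial graphs the
  bipartition can be suboptimal (the planted-graph suite demands ≥95%
  agreement with the exhaustive optimum, not 100%).
- The spectral method inherits no formal compatibility guarantee; on
  compatible inputs it recovers the model empirically, but only the
  min-cut baseline carries the classical proof, and the package asserts
  display/triple properties for the baseline only.
- Supertree outputs carry no branch lengths on edges created by merging
  (lengths inside grafted source subtrees are preserved); trees without
  full annotation serialise as topology only.
- `all_mincuts` mode is intended for correctness cross-checks, not speed.
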