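# Methods

## Problem setting

All trees are binary phylogenies with uniquely labeled leaves: rooted
trees are strictly bifurcating (a single leaf is allowed, since a
completion target may be one leaf), unrooted trees have node degrees 1 or
3 and at least three leaves. The Robinson–Foulds (RF) distance between two
trees on the same leaf set is the *unhalved* cardinality of the symmetric
difference of their clade sets (rooted) or split sets (unrooted), with
trivial clades/splits included; for identical leaf sets the trivial
elements cancel, so the value agrees with conventions that exclude them.
Non-binary input is rejected rather than resolved: the completion theory
is stated for binary trees and polytomy semantics would be a guess.

A *completion* of *T* on a superset leaf set L′ is a tree on L′ whose
leaf-induced restriction to Le(*T*) equals *T*. Two distances between
trees with different leaf sets follow: RF(−) restricts both trees to the
shared leaves; RF(+) completes the smaller (or both) and compares on the
union after minimizing over completions.

## The one-tree solver

Given rooted *S*, *T* with Le(*T*) ⊆ Le(*S*), the solver works in four
phases:

1. **Coloring** (one post-order pass over *S*): a leaf is green if its
   label occurs in *T*, red otherwise; an internal node is red/green if
   both children are, blue otherwise. A blue node with exactly one red
   child is *marked*; the subtree under its red child is a maximal red
   subtree. A blue node can never have two red children (it would be red),
   a fact the tests assert.
2. **LCA mapping**: each green/blue node *v* of *S* maps to the least
   common ancestor in *T* of the *T*-present leaves below *v*. Computed
   bottom-up from the (up to two) non-red children, each step is one LCA
   query.
3. **Grafting**: traversing *S* in pre-order, a copy of each marked
   node's maximal red subtree is attached on the *current* parent edge of
   its mapped node in the evolving completion (a fresh root is created
   when the mapped node is the current root). Processing ancestors before
   descendants makes earlier grafts sit farther from the mapped node,
   which is the stacking order the optimality argument requires. Ties —
   several incomparable marked nodes mapping to the same target — are
   broken by the deterministic pre-order; any order achieves the optimum,
   so determinism is purely for reproducibility.
4. **Reporting**: the completed tree, its RF distance to *S*, the list of
   grafted leaf sets, and a provenance tag per internal node (original /
   grafted junction / copied red subtree), maintained during grafting so
   the structural claims about optimal completions are directly testable.

The unrooted variant roots both trees on the edge of the lexicographically
smallest leaf of *T*, runs the rooted solver, and suppresses the root. The
achieved RF value provably does not depend on the rooting leaf (the
returned topology may); the tests re-run the solver at every admissible
leaf and compare values.

## The two-tree (extraneous-free) solver

With partially overlapping leaf sets, unrestricted joint completion can
manufacture *extraneous* clades — clades mixing leaves private to each
tree with no shared leaf — that lower the distance while being supported
by neither input. The implemented problem forbids them. The solver
completes *T* on the union with respect to *S* (the one-tree machinery
with *S* colored by the shared leaf set), then completes *S* with respect
to that completion; both outputs are extraneous-free and the pair attains
the minimum over all extraneous-free pairs. At least one shared leaf is
required (with none, every completion pair is extraneous); the unrooted
variant needs two and roots at the smallest shared leaf. Solving the
*unrestricted* two-tree problem optimally is out of scope — no
polynomial-time algorithm is known — and the package only exposes a
brute-force reference for it on small instances.

## Numerical and engineering choices

* **RF computation** uses an interval-labelling scheme: leaves are
  numbered in DFS order of the first tree so that each of its clades is a
  contiguous index interval; a clade of the second tree matches iff its
  index range is contiguous, saturated, and present in the first tree's
  interval set. This is linear-time and exact. Unrooted RF roots both
  trees at the shared smallest leaf and uses the rooted scheme, exact by
  the split/clade bijection under a common leaf rooting (also verified in
  tests against direct split-set comparison and against dendropy).
* **LCA index**: Euler tour plus sparse-table range-minimum (numpy),
  O(n log n) build and O(1) query. A true O(n) build exists but the log
  factor is irrelevant at the scales exercised and the simpler structure
  is easier to verify.
* **Label handling**: plain hash maps from labels to nodes; no
  integer-relabelling or perfect hashing is attempted, so the complexity
  guarantee is expected rather than worst-case — immaterial in practice.
* **Newick dialect**: branch lengths, internal labels and comments are
  parsed (via dendropy) and discarded; output is deterministic, ordering
  children by their lexicographically smallest descendant leaf, and never
  emits lengths. Unrooted trees serialize as a trifurcation centred on
  the internal node adjacent to the smallest leaf. Rootedness is always an
  explicit flag, never inferred from the string; a bifurcating base in
  unrooted mode is accepted and suppressed.
* **Optimal completions are not unique**: solvers return the
  deterministically constructed optimum and are compared in tests by RF
  value, validity and extraneous-freeness, never by serialization.

## Oracles

The brute-force references enumerate completions by inserting missing
leaves sequentially at every edge (plus the above-root position for rooted
trees), possibly emitting duplicate topologies — harmless for
minimization, deduplicated by canonical clade/split sets where pairs are
enumerated. Hard size guards (12 leaves single-tree, 10-leaf unions for
pairs) raise errors rather than warn. The pair oracle filters each side
independently for extraneous clades before pairing, which is valid because
extraneousness of a completion depends only on that tree and the two
original leaf sets.

## Synthetic instances and the ranking experiment

The generator grows a uniformly attached binary "true" tree (each new
leaf inserted at a uniformly chosen position), restricts it to two
overlapping leaf subsets, and perturbs the second restriction with leaf
prune–regraft moves (remove a random leaf, re-insert at a random
position). Defaults emulate the structure of completion inputs —
controlled overlap, controlled discordance — not any particular empirical
dataset: real supertree inputs have correlated taxon sampling, and real
discordance is not uniform leaf movement, so passing tests demonstrate
algorithmic correctness on the stated model, not biological realism.
Instance sweeps for oracle cross-validation draw 4–7 union leaves with
1–3 missing (one-tree problems) and 5–8 union leaves with 1–2 private
leaves per side (two-tree problems), with up to three prune–regraft
moves — small enough for exhaustive enumeration, large enough to exercise
every code path; hundreds of instances per problem run in seconds.

The ranking experiment computes RF(−) and RF(+) from each input tree to a
supertree and counts pairs whose orderings are opposite (Type-1), tied
only under RF(−) (Type-2), or tied only under RF(+) (Type-3); pairs tied
under both fall in no class, per the literal definitions. Percentages are
rounded half-up to two decimals. The published ranking studies used
supertrees estimated from real data; here any tree on a superset of the
inputs' leaves can serve, and the synthetic pipeline uses the true tree,
since the classification arithmetic is independent of the supertree's
origin. The raw Type-1/2/3 counts of those studies are not reproducible
without their datasets and supertree method; the package recomputes only
the derived totals and percentages from the published counts.

## Scale

The large-instance check completes a 100,000-leaf reference tree with
50,000 missing leaves in a few seconds on one CPU — consistent with the
near-linear design and far from any quadratic behaviour. All traversals
are iterative, so deep trees do not hit recursion limits.

## Known limitations

* Multifurcating trees, weighted (branch-length) RF, and tree drawing are
  unsupported.
* The unrestricted two-tree optimum is only available by brute force on
  tiny instances.
* Enumeration-based oracles grow exponentially and are hard-capped.
* The completion returned among co-optimal topologies is an algorithmic
  artifact (deterministic, but not canonicalized).
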