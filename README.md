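# rfplus — optimal tree completion under Robinson–Foulds distance

Comparing two phylogenetic trees is routine when they share a leaf set, but
real collections of trees — supertree inputs, gene trees, database queries —
rarely do. The traditional fix restricts both trees to their common leaves
and compares the prunings (the **RF(−)** distance), discarding whatever the
private leaves say about the shared topology. The alternative implemented
here *completes* each tree by optimally placing its missing leaves and
compares the results on the full leaf set (the **RF(+)** distance), which
uses all of the topological information and gives every tree the same
distance range regardless of its size.

`rfplus` provides linear-time (up to the logarithmic factor of the LCA
index) solvers for:

* **Rooted/unrooted one-tree completion** — given binary trees *S* and *T*
  with Le(*T*) ⊆ Le(*S*), find a completion *T′* of *T* on Le(*S*)
  minimizing RF(*S*, *T′*), where RF is the size of the symmetric
  difference of clade sets (rooted) or split sets (unrooted).
* **Extraneous-free two-tree completion** — for partially overlapping leaf
  sets, complete *both* trees on Le(*S*) ∪ Le(*T*) minimizing
  RF(*S′*, *T′*) over all completion pairs that contain no *extraneous*
  clade/split (one mixing leaves private to each tree without any shared
  leaf — such clades can lower the distance but are unsupported by either
  input topology).

The one-tree solver colors each node of *S* **green** (all descendant
leaves present in *T*), **red** (none present) or **blue** (mixed), maps
every green/blue node *v* to lca_T(Le(*S*(*v*)) ∩ Le(*T*)) with a
constant-time LCA index, and grafts a copy of each maximal red subtree —
one per blue node with exactly one red child — onto the parent edge of its
mapped node, in pre-order of *S*. The unrooted problems reduce to the
rooted ones by rooting both trees on the edge of a shared leaf; the
two-tree problem runs the one-tree machinery twice (*T* completed with
respect to *S*, then *S* with respect to that completion).

The package also ships exhaustive brute-force oracles (for verifying
optimality on small instances), a synthetic instance generator, and the
RF(−)/RF(+) ranking experiment with Type-1/2/3 pair classification
(pairs ranked oppositely by the two distances / tied only under RF(−) /
tied only under RF(+)).

## Worked example

`S = ((a,b),(c,d))` and `T = ((a,c),b)`; leaf `d` is missing from `T`.

```sh
$ rfplus complete1 --rooted -s S.nwk -t T.nwk -o out.nwk --report r.json
$ cat out.nwk
((a,(c,d)),b);
$ cat r.json
{
  "n_grafts": 1,
  "n_leaves_S": 4,
  "n_leaves_T": 3,
  "problem": "one-tree-completion",
  "rf": 2,
  "rooting_leaf": null
}
```

The solver grafts `d` as the sibling of `c` (the node `c` maps to under
the LCA mapping), producing `((a,(c,d)),b)` at RF distance 2 from `S` —
the minimum over all five possible placements of `d`, as the brute-force
oracle confirms (`--oracle`). The same interfaces exist in Python:

```python
>>> from rfplus import parse_newick, two_tree_completion_ef, write_newick
>>> S = parse_newick("((a,b),(c,x));", rooted=True)   # x private to S
>>> T = parse_newick("((a,c),(b,y));", rooted=True)   # y private to T
>>> res = two_tree_completion_ef(S, T)
>>> res.rf, write_newick(res.completed_s), write_newick(res.completed_t)
(2, '((a,(b,y)),(c,x));', '((a,(c,x)),(b,y));')
```

Both completions are on the union `{a,b,c,x,y}`, restrict back to their
inputs, contain no extraneous clade, and no extraneous-free pair does
better than RF = 2.

Other subcommands: `rfplus rf` (RF(−)/RF(+) between two trees),
`rfplus simulate` (synthetic instances), `rfplus rank` (rank input trees
against a supertree and classify pairs).

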