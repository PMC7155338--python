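"""Binary phylogenetic tree model and topological primitives.

This module houses the data structures and operations everything else is
built on: rooted and unrooted binary trees with uniquely labeled leaves,
Newick input/output, leaf-induced restriction, clade and split extraction,
the Robinson-Foulds (RF) distance, a constant-time LCA index, and the
rooted/unrooted conversions used by the unrooted solvers.

Conventions
-----------
* Rooted trees are strictly bifurcating (every internal node has exactly
  two children); a single leaf is a valid rooted tree.
* Unrooted trees have nodes of degree 1 (leaves) or 3 only and require at
  least three leaves.
* Branch lengths, internal node labels and Newick comments are parsed and
  discarded: every operation here is purely topological.
* RF distance is the *unhalved* cardinality of the symmetric difference of
  clade sets (rooted) or split sets (unrooted), with trivial clades/splits
  included. For trees on the same leaf set the trivial elements cancel, so
  the value agrees with conventions that exclude them.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "PhyloError",
    "NewickParseError",
    "InvalidTreeError",
    "LeafSetError",
    "RNode",
    "UNode",
    "RootedPhylo",
    "UnrootedPhylo",
    "LcaIndex",
    "parse_newick",
    "write_newick",
    "restrict",
    "clade_set",
    "split_set",
    "rf_distance",
    "lca_build",
    "root_at_leaf",
    "unroot",
    "trees_equal",
]

#: Characters with syntactic meaning in Newick; forbidden inside leaf labels.
RESERVED_LABEL_CHARS = set("(),;:[]'\"")


class PhyloError(Exception):
    """Base class for all errors raised by this package."""


class NewickParseError(PhyloError):
    """Malformed Newick input."""


class InvalidTreeError(PhyloError):
    """Input violates the binary-tree / unique-label invariants."""


class LeafSetError(PhyloError):
    """A leaf-set precondition (subset, overlap, size) is violated."""


# ---------------------------------------------------------------------------
# Node and tree containers
# ---------------------------------------------------------------------------


class RNode:
    """Node of a rooted binary tree. Leaves carry a label, internals do not."""

    __slots__ = ("parent", "children", "label")

    def __init__(self, label: str | None = None):
        self.parent: RNode | None = None
        self.children: list[RNode] = []
        self.label = label

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "RNode") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<RNode leaf {self.label!r}>" if self.is_leaf else "<RNode internal>"


class UNode:
    """Node of an unrooted binary tree (degree 1 or 3)."""

    __slots__ = ("neighbors", "label")

    def __init__(self, label: str | None = None):
        self.neighbors: list[UNode] = []
        self.label = label

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<UNode leaf {self.label!r}>" if self.is_leaf else "<UNode internal>"


def _link(a: UNode, b: UNode) -> None:
    a.neighbors.append(b)
    b.neighbors.append(a)


def _unlink(a: UNode, b: UNode) -> None:
    a.neighbors.remove(b)
    b.neighbors.remove(a)


class RootedPhylo:
    """A rooted binary tree with uniquely labeled leaves.

    Node identities are internal; all external exchange is by leaf label.
    Iteration orders (pre/post-order) follow the stored child order and are
    deterministic for a deterministically constructed tree.
    """

    def __init__(self, root: RNode):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[RNode]:
        out: list[RNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[RNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> Iterator[RNode]:
        return (n for n in self.postorder() if n.is_leaf)

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())

    def label_map(self) -> dict[str, RNode]:
        return {n.label: n for n in self.leaves()}

    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    # -- copying -----------------------------------------------------------

    def copy(self) -> tuple["RootedPhylo", dict[RNode, RNode]]:
        """Deep-copy the tree; returns (copy, old-node -> new-node map)."""
        new_root, mapping = copy_subtree(self.root)
        return RootedPhylo(new_root), mapping

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Raise InvalidTreeError if any structural invariant is violated."""
        seen_labels: set[str] = set()
        n_leaves = n_internal = 0
        for node in self.postorder():
            if node.is_leaf:
                n_leaves += 1
                _check_label(node.label)
                if node.label in seen_labels:
                    raise InvalidTreeError(f"duplicate leaf label {node.label!r}")
                seen_labels.add(node.label)
            else:
                n_internal += 1
                if len(node.children) != 2:
                    raise InvalidTreeError(
                        "rooted tree is not binary: internal node with "
                        f"{len(node.children)} children"
                    )
                for c in node.children:
                    if c.parent is not node:
                        raise InvalidTreeError("parent/child pointers inconsistent")
        if self.root.parent is not None:
            raise InvalidTreeError("root has a parent")
        if n_leaves >= 2 and n_internal != n_leaves - 1:
            raise InvalidTreeError("node count inconsistent with binary invariant")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RootedPhylo({write_newick(self)!r})"


class UnrootedPhylo:
    """An unrooted binary tree (degrees 1/3) with uniquely labeled leaves.

    The tree is held by an anchor node; traversal explores the adjacency
    structure from there. Mutating helpers keep the anchor valid.
    """

    def __init__(self, anchor: UNode):
        self.anchor = anchor

    def nodes(self) -> Iterator[UNode]:
        seen = {id(self.anchor)}
        stack = [self.anchor]
        while stack:
            node = stack.pop()
            yield node
            for nb in node.neighbors:
                if id(nb) not in seen:
                    seen.add(id(nb))
                    stack.append(nb)

    def leaves(self) -> Iterator[UNode]:
        return (n for n in self.nodes() if n.is_leaf)

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())

    def label_map(self) -> dict[str, UNode]:
        return {n.label: n for n in self.leaves()}

    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def edges(self) -> list[tuple[UNode, UNode]]:
        """Deterministic list of edges (each once)."""
        out: list[tuple[UNode, UNode]] = []
        seen: set[int] = set()
        for node in self.nodes():
            seen.add(id(node))
            for nb in node.neighbors:
                if id(nb) not in seen:
                    out.append((node, nb))
        return out

    def copy(self) -> tuple["UnrootedPhylo", dict[UNode, UNode]]:
        mapping: dict[UNode, UNode] = {}
        for node in self.nodes():
            mapping[node] = UNode(node.label)
        done: set[int] = set()
        for node in mapping:
            done.add(id(node))
            for nb in node.neighbors:
                if id(nb) not in done:
                    _link(mapping[node], mapping[nb])
        return UnrootedPhylo(mapping[self.anchor]), mapping

    def validate(self) -> None:
        seen_labels: set[str] = set()
        n_nodes = n_leaves = 0
        degree_sum = 0
        for node in self.nodes():
            n_nodes += 1
            deg = len(node.neighbors)
            degree_sum += deg
            if node.is_leaf:
                n_leaves += 1
                _check_label(node.label)
                if deg != 1:
                    raise InvalidTreeError("labeled node with degree != 1")
                if node.label in seen_labels:
                    raise InvalidTreeError(f"duplicate leaf label {node.label!r}")
                seen_labels.add(node.label)
            elif deg != 3:
                raise InvalidTreeError(f"internal node with degree {deg} (expected 3)")
        if n_leaves < 3:
            raise InvalidTreeError("unrooted tree needs at least 3 leaves")
        # connected by construction of nodes(); acyclic iff |E| = |V| - 1
        if degree_sum != 2 * (n_nodes - 1):
            raise InvalidTreeError("graph is not a tree (edge count mismatch)")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"UnrootedPhylo({write_newick(self)!r})"


def copy_subtree(node: RNode) -> tuple[RNode, dict[RNode, RNode]]:
    """Copy the rooted subtree at ``node``; the copy's root has no parent."""
    mapping: dict[RNode, RNode] = {}
    stack = [node]
    while stack:
        cur = stack.pop()
        mapping[cur] = RNode(cur.label)
        stack.extend(cur.children)
    for cur, new in mapping.items():
        for c in cur.children:
            new.add_child(mapping[c])
    mapping[node].parent = None
    return mapping[node], mapping


def _check_label(label: str | None) -> None:
    if not label:
        raise InvalidTreeError("empty leaf label")
    bad = set(label) & RESERVED_LABEL_CHARS
    if bad:
        raise InvalidTreeError(
            f"leaf label {label!r} contains reserved Newick characters {sorted(bad)}"
        )


# ---------------------------------------------------------------------------
# Newick input (via dendropy) and deterministic output
# ---------------------------------------------------------------------------


def parse_newick(text: str, rooted: bool) -> RootedPhylo | UnrootedPhylo:
    """Parse a single Newick statement into a tree of the requested rootedness.

    Rootedness is never inferred from the string: ``rooted=True`` demands a
    strictly bifurcating representation, ``rooted=False`` accepts the standard
    basal trifurcation (a bifurcating base is also accepted and suppressed).
    Branch lengths, internal labels and ``[...]`` comments are discarded.
    """
    import dendropy

    if not isinstance(text, str) or ";" not in text:
        raise NewickParseError("input is not a ';'-terminated Newick statement")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "uplicate" in str(exc):  # duplicate taxon: invariant, not syntax
            raise InvalidTreeError(f"duplicate leaf label: {exc}") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    if rooted:
        tree = RootedPhylo(_convert_rooted(dtree.seed_node))
        tree.validate()
        return tree
    return _convert_unrooted(dtree.seed_node)


def _leaf_label_of(dnode) -> str:
    if dnode.taxon is None or dnode.taxon.label is None:
        raise InvalidTreeError("unlabeled leaf in Newick input")
    return dnode.taxon.label


def _convert_rooted(seed) -> RNode:
    mapping: dict[int, RNode] = {}
    stack = [seed]
    order = []
    while stack:
        d = stack.pop()
        order.append(d)
        stack.extend(d.child_nodes())
    for d in order:
        kids = d.child_nodes()
        if kids and len(kids) != 2:
            raise InvalidTreeError(
                f"rooted input is not strictly bifurcating (node with {len(kids)} children)"
            )
        mapping[id(d)] = RNode(None if kids else _leaf_label_of(d))
    for d in order:
        for c in d.child_nodes():
            mapping[id(d)].add_child(mapping[id(c)])
    return mapping[id(seed)]


def _convert_unrooted(seed) -> UnrootedPhylo:
    mapping: dict[int, UNode] = {}
    order = []
    stack = [seed]
    while stack:
        d = stack.pop()
        order.append(d)
        stack.extend(d.child_nodes())
    for d in order:
        kids = d.child_nodes()
        mapping[id(d)] = UNode(None if kids else _leaf_label_of(d))
    for d in order:
        for c in d.child_nodes():
            _link(mapping[id(d)], mapping[id(c)])
    base = mapping[id(seed)]
    if len(base.neighbors) == 2:  # rooted-style serialization: suppress the base
        a, b = base.neighbors
        _unlink(base, a)
        _unlink(base, b)
        _link(a, b)
        base = a
    tree = UnrootedPhylo(base)
    tree.validate()
    return tree


def _min_labels_rooted(tree: RootedPhylo) -> dict[RNode, str]:
    ml: dict[RNode, str] = {}
    for node in tree.postorder():
        ml[node] = node.label if node.is_leaf else min(ml[c] for c in node.children)
    return ml


def _serialize(root_item, children_of) -> str:
    """Iterative Newick body serializer over a directed view of the tree."""
    parts: list[str] = []
    stack: list[tuple[str, object]] = [("node", root_item)]
    while stack:
        kind, item = stack.pop()
        if kind == "tok":
            parts.append(item)  # type: ignore[arg-type]
            continue
        kids, label = children_of(item)
        if not kids:
            parts.append(label)
        else:
            parts.append("(")
            frame: list[tuple[str, object]] = []
            for i, c in enumerate(kids):
                if i:
                    frame.append(("tok", ","))
                frame.append(("node", c))
            frame.append(("tok", ")"))
            stack.extend(reversed(frame))
    return "".join(parts)


def write_newick(tree: RootedPhylo | UnrootedPhylo) -> str:
    """Serialize deterministically: children appear in lexicographic order of
    their smallest descendant leaf label; no branch lengths are emitted.

    Unrooted trees are written as a basal trifurcation centred on the
    internal node adjacent to the lexicographically smallest leaf.
    """
    if isinstance(tree, RootedPhylo):
        ml = _min_labels_rooted(tree)

        def children_of(node: RNode):
            kids = sorted(node.children, key=lambda c: ml[c])
            return kids, node.label

        return _serialize(tree.root, children_of) + ";"

    if not isinstance(tree, UnrootedPhylo):
        raise TypeError("expected RootedPhylo or UnrootedPhylo")
    smallest = min(tree.leaves(), key=lambda n: n.label)
    center = smallest.neighbors[0]
    # directed view: items are (node, came_from); compute min labels per
    # directed edge on demand via memoized recursion-free evaluation
    ml_dir: dict[tuple[int, int], str] = {}

    def min_label(node: UNode, parent: UNode) -> str:
        key = (id(node), id(parent))
        if key in ml_dir:
            return ml_dir[key]
        # iterative post-order over the directed subtree
        stack: list[tuple[UNode, UNode, bool]] = [(node, parent, False)]
        while stack:
            cur, par, expanded = stack.pop()
            k = (id(cur), id(par))
            if k in ml_dir:
                continue
            if cur.is_leaf:
                ml_dir[k] = cur.label
            elif expanded:
                ml_dir[k] = min(
                    ml_dir[(id(nb), id(cur))] for nb in cur.neighbors if nb is not par
                )
            else:
                stack.append((cur, par, True))
                for nb in cur.neighbors:
                    if nb is not par:
                        stack.append((nb, cur, False))
        return ml_dir[key]

    def children_of(item):
        node, parent = item
        if node.is_leaf:
            return [], node.label
        kids = [(nb, node) for nb in node.neighbors if nb is not parent]
        kids.sort(key=lambda it: min_label(*it))
        return kids, None

    return _serialize((center, None), children_of) + ";"


# ---------------------------------------------------------------------------
# Leaf-induced restriction
# ---------------------------------------------------------------------------


def restrict(
    tree: RootedPhylo | UnrootedPhylo, labels: Iterable[str]
) -> RootedPhylo | UnrootedPhylo:
    """Leaf-induced subtree T[L]: the minimal subtree spanning the leaves in
    ``labels`` with all degree-two non-root nodes suppressed."""
    L = frozenset(labels)
    have = tree.leaf_labels()
    if not L <= have:
        raise LeafSetError(f"labels {sorted(L - have)} are not leaves of the tree")
    if isinstance(tree, RootedPhylo):
        if len(L) < 1:
            raise LeafSetError("rooted restriction needs at least 1 leaf")
        new: dict[RNode, RNode] = {}
        for node in tree.postorder():
            if node.is_leaf:
                if node.label in L:
                    new[node] = RNode(node.label)
            else:
                kept = [new[c] for c in node.children if c in new]
                if len(kept) == 1:
                    new[node] = kept[0]  # suppress degree-two node
                elif len(kept) == 2:
                    inner = RNode()
                    for k in kept:
                        inner.add_child(k)
                    new[node] = inner
        return RootedPhylo(new[tree.root])
    if len(L) < 3:
        raise LeafSetError("unrooted restriction needs at least 3 leaves")
    anchor_label = min(L)
    rooted = root_at_leaf(tree, anchor_label)
    return unroot(restrict(rooted, L))


# ---------------------------------------------------------------------------
# Clades, splits and the RF distance
# ---------------------------------------------------------------------------


def clade_set(tree: RootedPhylo) -> frozenset[frozenset[str]]:
    """All clades of a rooted tree (one per node, singletons and the full
    leaf set included)."""
    clades: dict[RNode, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            clades[node] = frozenset((node.label,))
        else:
            clades[node] = frozenset().union(*(clades[c] for c in node.children))
    return frozenset(clades.values())


def split_set(tree: UnrootedPhylo) -> frozenset[frozenset[str]]:
    """All splits of an unrooted tree, one per edge, each canonicalized as
    the side *not* containing the lexicographically smallest leaf label."""
    smallest = min(tree.leaf_labels())
    rooted = root_at_leaf(tree, smallest)
    full = tree.leaf_labels()
    trivial_excluded = {frozenset((smallest,)), full}
    return frozenset(c for c in clade_set(rooted) if c not in trivial_excluded)


def _rf_rooted(a: RootedPhylo, b: RootedPhylo) -> int:
    # Day-style interval labelling: number A's leaves in DFS order so every
    # clade of A is a contiguous index interval; a clade of B matches one of
    # A iff its index range is contiguous, full, and present in A.
    order: dict[str, int] = {}
    intervals_a: dict[RNode, tuple[int, int]] = {}
    n_a = 0
    for node in a.postorder():
        n_a += 1
        if node.is_leaf:
            order[node.label] = len(order)
            intervals_a[node] = (order[node.label], order[node.label])
        else:
            lo = min(intervals_a[c][0] for c in node.children)
            hi = max(intervals_a[c][1] for c in node.children)
            intervals_a[node] = (lo, hi)
    set_a = set(intervals_a.values())

    common = 0
    n_b = 0
    info: dict[RNode, tuple[int, int, int]] = {}
    for node in b.postorder():
        n_b += 1
        if node.is_leaf:
            i = order[node.label]
            info[node] = (i, i, 1)
        else:
            lo = min(info[c][0] for c in node.children)
            hi = max(info[c][1] for c in node.children)
            size = sum(info[c][2] for c in node.children)
            info[node] = (lo, hi, size)
        lo, hi, size = info[node]
        if hi - lo + 1 == size and (lo, hi) in set_a:
            common += 1
    return (n_a - common) + (n_b - common)


def rf_distance(
    a: RootedPhylo | UnrootedPhylo, b: RootedPhylo | UnrootedPhylo
) -> int:
    """Robinson-Foulds distance: |Clade(a) xor Clade(b)| for rooted trees,
    |Split(a) xor Split(b)| for unrooted trees (unhalved, trivial elements
    included). Requires identical leaf sets and matching rootedness."""
    rooted_a = isinstance(a, RootedPhylo)
    rooted_b = isinstance(b, RootedPhylo)
    if rooted_a != rooted_b:
        raise LeafSetError("cannot compare a rooted tree with an unrooted tree")
    la, lb = a.leaf_labels(), b.leaf_labels()
    if la != lb:
        raise LeafSetError("RF distance requires identical leaf sets")
    if rooted_a:
        return _rf_rooted(a, b)
    # root both at the same (smallest) leaf: the split<->clade bijection under
    # a common leaf rooting makes the rooted value equal the unrooted one
    l = min(la)
    return _rf_rooted(root_at_leaf(a, l), root_at_leaf(b, l))


def trees_equal(
    a: RootedPhylo | UnrootedPhylo, b: RootedPhylo | UnrootedPhylo
) -> bool:
    """True iff same rootedness, identical leaf sets and identical clade
    (rooted) or split (unrooted) sets; child order is immaterial."""
    if isinstance(a, RootedPhylo) != isinstance(b, RootedPhylo):
        raise LeafSetError("cannot compare a rooted tree with an unrooted tree")
    if a.leaf_labels() != b.leaf_labels():
        return False
    return rf_distance(a, b) == 0


# ---------------------------------------------------------------------------
# LCA index (Euler tour + sparse-table RMQ)
# ---------------------------------------------------------------------------


class LcaIndex:
    """Constant-time LCA queries on a rooted tree after O(n log n) build.

    Valid only for the exact tree object it was built on; grafting into a
    *copy* of that tree (as the completion solvers do) leaves the index
    intact.
    """

    def __init__(self, tree: RootedPhylo):
        self.tree = tree
        depth: dict[RNode, int] = {tree.root: 0}
        for node in tree.preorder():
            for c in node.children:
                depth[c] = depth[node] + 1

        euler: list[RNode] = []
        depths: list[int] = []
        first: dict[int, int] = {}
        self._by_id: dict[int, RNode] = {}

        def visit(n: RNode) -> None:
            if id(n) not in first:
                first[id(n)] = len(euler)
                self._by_id[id(n)] = n
            euler.append(n)
            depths.append(depth[n])

        stack: list[list] = [[tree.root, 0]]
        visit(tree.root)
        while stack:
            node, ci = stack[-1]
            if ci < len(node.children):
                stack[-1][1] += 1
                child = node.children[ci]
                visit(child)
                stack.append([child, 0])
            else:
                stack.pop()
                if stack:
                    visit(stack[-1][0])

        self._euler = euler
        self._first = first
        d = np.asarray(depths, dtype=np.int32)
        m = len(d)
        k_max = max(1, m.bit_length())
        table = np.zeros((k_max, m), dtype=np.int32)
        table[0] = np.arange(m, dtype=np.int32)
        j = 1
        while (1 << j) <= m:
            span = 1 << j
            half = 1 << (j - 1)
            left = table[j - 1, : m - span + 1]
            right = table[j - 1, half : m - span + 1 + half]
            table[j, : m - span + 1] = np.where(d[left] <= d[right], left, right)
            j += 1
        self._depths = d
        self._table = table

    def query(self, u: RNode, v: RNode) -> RNode:
        """Least common ancestor of two nodes of the indexed tree."""
        try:
            i, j = self._first[id(u)], self._first[id(v)]
        except KeyError:
            raise PhyloError("node does not belong to the indexed tree") from None
        if i > j:
            i, j = j, i
        k = (j - i + 1).bit_length() - 1
        a = int(self._table[k, i])
        b = int(self._table[k, j - (1 << k) + 1])
        best = a if self._depths[a] <= self._depths[b] else b
        return self._euler[best]


def lca_build(tree: RootedPhylo) -> LcaIndex:
    """Build an :class:`LcaIndex` for ``tree``."""
    return LcaIndex(tree)


# ---------------------------------------------------------------------------
# Rooted <-> unrooted conversions
# ---------------------------------------------------------------------------


def root_at_leaf(tree: UnrootedPhylo, label: str) -> RootedPhylo:
    """Root an unrooted tree on the edge incident to leaf ``label``.

    The new root subdivides that edge; its two children are the leaf and the
    rest of the tree.
    """
    lmap = tree.label_map()
    if label not in lmap:
        raise LeafSetError(f"leaf {label!r} not present in tree")
    leaf = lmap[label]
    start = leaf.neighbors[0]

    root = RNode()
    root.add_child(RNode(label))

    new_of: dict[int, RNode] = {}
    stack: list[tuple[UNode, UNode, RNode]] = [(start, leaf, root)]
    while stack:
        unode, came_from, rparent = stack.pop()
        rnode = RNode(unode.label)
        new_of[id(unode)] = rnode
        rparent.add_child(rnode)
        for nb in unode.neighbors:
            if nb is not came_from:
                stack.append((nb, unode, rnode))
    # fix child order: stack-based expansion appended in reverse
    for rnode in new_of.values():
        rnode.children.reverse()
    return RootedPhylo(root)


def _unroot_with_map(
    tree: RootedPhylo,
) -> tuple[UnrootedPhylo, dict[RNode, UNode]]:
    if tree.n_leaves() < 3:
        raise LeafSetError("unrooting requires at least 3 leaves")
    mapping: dict[RNode, UNode] = {}
    for node in tree.postorder():
        mapping[node] = UNode(node.label)
    for node in tree.postorder():
        for c in node.children:
            _link(mapping[node], mapping[c])
    root_u = mapping[tree.root]
    a, b = list(root_u.neighbors)
    _unlink(root_u, a)
    _unlink(root_u, b)
    _link(a, b)
    del mapping[tree.root]
    return UnrootedPhylo(a), mapping


def unroot(tree: RootedPhylo) -> UnrootedPhylo:
    """Suppress the root of a rooted tree (>= 3 leaves), joining its two
    children by an edge."""
    utree, _ = _unroot_with_map(tree)
    return utree


# ---------------------------------------------------------------------------
# Small mutation helpers shared by the oracle and the instance generator
# ---------------------------------------------------------------------------


def insert_leaf_unrooted(
    tree: UnrootedPhylo, edge: tuple[UNode, UNode], label: str
) -> UNode:
    """Attach a new leaf on ``edge`` by subdividing it (in place); returns
    the new leaf node."""
    u, v = edge
    mid = UNode()
    _unlink(u, v)
    _link(u, mid)
    _link(mid, v)
    leaf = UNode(label)
    _link(mid, leaf)
    return leaf


def prune_leaf_unrooted(tree: UnrootedPhylo, leaf: UNode) -> None:
    """Remove a leaf and suppress the resulting degree-two node (in place).

    The tree must keep >= 3 leaves afterwards.
    """
    mid = leaf.neighbors[0]
    _unlink(leaf, mid)
    a, b = mid.neighbors
    _unlink(mid, a)
    _unlink(mid, b)
    _link(a, b)
    if tree.anchor is leaf or tree.anchor is mid:
        tree.anchor = a
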