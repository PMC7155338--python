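"""Optimal tree completion under Robinson-Foulds distance.

Four solvers are provided:

* :func:`one_tree_completion` — rooted one-tree completion: given rooted
  binary trees ``S`` and ``T`` with ``Le(T) ⊆ Le(S)``, add the missing
  leaves to ``T`` so that the RF distance to ``S`` is minimized over all
  completions.
* :func:`uot_completion` — the unrooted analog, solved by rooting both
  trees on the edge of a shared leaf, completing, and suppressing the root.
* :func:`two_tree_completion_ef` — extraneous-clade-free two-tree
  completion for rooted trees with partially overlapping leaf sets: both
  trees are completed to the union leaf set, minimizing their mutual RF
  distance over all completion pairs in which no clade mixes leaves private
  to each tree without containing a shared leaf.
* :func:`ef_u_completion` — the unrooted (extraneous-split-free) analog.

The one-tree solver runs in four phases: (1) color every node of ``S``
green (all descendant leaves shared), red (none shared) or blue (mixed),
marking blue nodes with exactly one red child; (2) map every green/blue
node of ``S`` to the least common ancestor in ``T`` of its shared leaves;
(3) traverse ``S`` in pre-order and, at each marked node, graft a copy of
its maximal red subtree onto the current parent edge of the mapped node in
the evolving completion; (4) report the completed tree and its RF distance.
Each maximal red subtree is grafted exactly once, so the whole procedure is
linear in the tree sizes up to the logarithmic factor of the LCA build.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

from .tree_model import (
    LcaIndex,
    LeafSetError,
    PhyloError,
    RNode,
    RootedPhylo,
    UNode,
    UnrootedPhylo,
    _unroot_with_map,
    clade_set,
    copy_subtree,
    lca_build,
    rf_distance,
    root_at_leaf,
)

__all__ = [
    "Color",
    "Provenance",
    "NodeColoring",
    "CompletionOne",
    "CompletionTwo",
    "color_and_mark",
    "lca_mapping",
    "tree_add",
    "one_tree_completion",
    "uot_completion",
    "is_extraneous_clade",
    "find_extraneous",
    "two_tree_completion_ef",
    "ef_u_completion",
]


class Color(enum.Enum):
    """Node color w.r.t. a reference leaf set: green = all descendant leaves
    shared, red = none shared, blue = mixed."""

    GREEN = "green"
    RED = "red"
    BLUE = "blue"


class Provenance(enum.Enum):
    """Origin of an internal node of a completed tree."""

    ORIGINAL = "original"
    GRAFTED = "grafted"
    COPIED_RED = "copied-red-subtree"


@dataclass(frozen=True)
class NodeColoring:
    """Green/red/blue coloring of a rooted tree induced by a leaf set.

    ``marked`` is the set of blue nodes with exactly one red child; the red
    child of a marked node roots a maximal red subtree, the unit of
    grafting.
    """

    color: dict[RNode, Color]
    marked: frozenset[RNode]
    source_leaves: frozenset[str]


@dataclass
class CompletionOne:
    """Result of a one-tree completion.

    ``completed`` restricts back to the input tree on its original leaves;
    ``rf`` is the achieved (minimal) RF distance to the reference tree;
    ``provenance`` classifies every internal node of ``completed``;
    ``grafts`` lists the leaf sets of the grafted maximal red subtrees in
    the order they were attached; ``rooting_leaf`` records the leaf used by
    the unrooted reduction (None for rooted runs).
    """

    completed: RootedPhylo | UnrootedPhylo
    rf: int
    provenance: dict[object, Provenance]
    grafts: tuple[frozenset[str], ...]
    rooting_leaf: str | None = None
    n_grafts: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_grafts = len(self.grafts)


@dataclass
class CompletionTwo:
    """Result of an extraneous-free two-tree completion (both trees on the
    union leaf set)."""

    completed_s: RootedPhylo | UnrootedPhylo
    completed_t: RootedPhylo | UnrootedPhylo
    rf: int
    provenance_s: dict[object, Provenance]
    provenance_t: dict[object, Provenance]
    grafts_s: tuple[frozenset[str], ...]
    grafts_t: tuple[frozenset[str], ...]
    rooting_leaf: str | None = None


# ---------------------------------------------------------------------------
# Phase 1: coloring and marking
# ---------------------------------------------------------------------------


def color_and_mark(S: RootedPhylo, t_leaves: Iterable[str]) -> NodeColoring:
    """Color the nodes of ``S`` relative to ``t_leaves`` in one post-order
    pass and mark every blue node with exactly one red child."""
    tset = frozenset(t_leaves)
    if not tset:
        raise LeafSetError("reference leaf set is empty")
    if not tset <= S.leaf_labels():
        raise LeafSetError("reference leaves are not a subset of the tree's leaves")
    color: dict[RNode, Color] = {}
    marked: set[RNode] = set()
    for node in S.postorder():
        if node.is_leaf:
            color[node] = Color.GREEN if node.label in tset else Color.RED
        else:
            kids = [color[c] for c in node.children]
            if all(k is Color.RED for k in kids):
                color[node] = Color.RED
            elif all(k is Color.GREEN for k in kids):
                color[node] = Color.GREEN
            else:
                color[node] = Color.BLUE
                if sum(1 for k in kids if k is Color.RED) == 1:
                    marked.add(node)
    return NodeColoring(color=color, marked=frozenset(marked), source_leaves=tset)


# ---------------------------------------------------------------------------
# Phase 2: LCA mapping
# ---------------------------------------------------------------------------


def lca_mapping(
    S: RootedPhylo, coloring: NodeColoring, T: RootedPhylo, idx: LcaIndex
) -> dict[RNode, RNode]:
    """Map every green/blue node ``v`` of ``S`` to the least common ancestor
    in ``T`` of the shared leaves below ``v``.

    Computed bottom-up: a green leaf maps to the like-labeled leaf of ``T``;
    an internal node maps to the LCA of its non-red children's mappings, a
    constant-time step per node given the LCA index on ``T``.
    """
    tmap = T.label_map()
    M: dict[RNode, RNode] = {}
    for v in S.postorder():
        col = coloring.color[v]
        if col is Color.RED:
            continue
        if v.is_leaf:
            try:
                M[v] = tmap[v.label]
            except KeyError:
                raise LeafSetError(
                    f"green leaf {v.label!r} has no counterpart in the target tree"
                ) from None
        else:
            maps = [M[c] for c in v.children if coloring.color[c] is not Color.RED]
            M[v] = maps[0] if len(maps) == 1 else idx.query(maps[0], maps[1])
    return M


# ---------------------------------------------------------------------------
# Phase 3: grafting
# ---------------------------------------------------------------------------


def _tree_add_node(tree: RootedPhylo, v: RNode, xroot: RNode) -> RNode:
    """In-place Tree-Add: attach ``xroot`` on the parent edge of ``v`` (or
    above the root); returns the newly created internal node."""
    new = RNode()
    if v is tree.root:
        new.add_child(v)
        new.add_child(xroot)
        new.parent = None
        tree.root = new
    else:
        parent = v.parent
        parent.children[parent.children.index(v)] = new
        new.parent = parent
        new.add_child(v)
        new.add_child(xroot)
    return new


def tree_add(tree: RootedPhylo, v: RNode, X: RootedPhylo) -> RootedPhylo:
    """Graft tree ``X`` onto the parent edge of node ``v`` of ``tree`` (or
    create a new root if ``v`` is the root), making ``rt(X)`` the sibling of
    ``v``. Mutates ``tree`` in place and returns it; ``X`` is absorbed.

    The leaf sets of ``tree`` and ``X`` must be disjoint and ``v`` must
    belong to ``tree``.
    """
    if tree.leaf_labels() & X.leaf_labels():
        raise LeafSetError("grafted tree shares leaf labels with the host tree")
    node = v
    while node.parent is not None:
        node = node.parent
    if node is not tree.root:
        raise PhyloError("node does not belong to the host tree")
    _tree_add_node(tree, v, X.root)
    return tree


def _graft_completion(
    S: RootedPhylo, T: RootedPhylo
) -> tuple[RootedPhylo, dict[RNode, Provenance], tuple[frozenset[str], ...]]:
    """Complete ``T`` on ``Le(S) ∪ Le(T)`` with respect to ``S``.

    ``S`` is colored by the shared leaf set; each maximal red subtree of
    ``S`` (holding leaves absent from ``T``) is copied and grafted, in
    pre-order of ``S``, onto the current parent edge of its LCA-mapped node
    in the evolving completion. Requires at least one shared leaf.
    """
    common = S.leaf_labels() & T.leaf_labels()
    if not common:
        raise LeafSetError("trees share no leaves; no completion is defined")
    coloring = color_and_mark(S, common)
    Tc, tmap = T.copy()
    provenance: dict[RNode, Provenance] = {
        n: Provenance.ORIGINAL for n in Tc.postorder() if not n.is_leaf
    }
    grafts: list[frozenset[str]] = []
    if coloring.marked:
        idx = lca_build(T)
        M = lca_mapping(S, coloring, T, idx)
        for v in S.preorder():
            if v not in coloring.marked:
                continue
            (red_child,) = [
                c for c in v.children if coloring.color[c] is Color.RED
            ]
            xroot, xmap = copy_subtree(red_child)
            target = tmap[M[v]]
            new_node = _tree_add_node(Tc, target, xroot)
            provenance[new_node] = Provenance.GRAFTED
            for new in xmap.values():
                if not new.is_leaf:
                    provenance[new] = Provenance.COPIED_RED
            grafts.append(
                frozenset(n.label for n in RootedPhylo(xroot).leaves())
            )
    return Tc, provenance, tuple(grafts)


# ---------------------------------------------------------------------------
# Phase 4: the solvers
# ---------------------------------------------------------------------------


def one_tree_completion(S: RootedPhylo, T: RootedPhylo) -> CompletionOne:
    """Optimal rooted one-tree completion: returns a completion ``T'`` of
    ``T`` on ``Le(S)`` minimizing ``RF(S, T')`` over all completions.

    Requires ``Le(T) ⊆ Le(S)`` with ``T`` non-empty. Optimal completions
    need not be unique; the deterministically constructed one is returned.
    """
    if not isinstance(S, RootedPhylo) or not isinstance(T, RootedPhylo):
        raise PhyloError("one_tree_completion expects rooted trees")
    if not T.leaf_labels() <= S.leaf_labels():
        raise LeafSetError("Le(T) must be a subset of Le(S)")
    completed, provenance, grafts = _graft_completion(S, T)
    return CompletionOne(
        completed=completed,
        rf=rf_distance(S, completed),
        provenance=provenance,
        grafts=grafts,
    )


def uot_completion(S: UnrootedPhylo, T: UnrootedPhylo) -> CompletionOne:
    """Optimal unrooted one-tree completion.

    Both trees are rooted on the edge of the lexicographically smallest
    leaf of ``T``, completed with the rooted solver, and the root is
    suppressed. The achieved RF value is independent of the choice of
    rooting leaf; the returned topology may depend on it.
    """
    if not isinstance(S, UnrootedPhylo) or not isinstance(T, UnrootedPhylo):
        raise PhyloError("uot_completion expects unrooted trees")
    if not T.leaf_labels() <= S.leaf_labels():
        raise LeafSetError("Le(T) must be a subset of Le(S)")
    if T.n_leaves() < 3 or S.n_leaves() < 3:
        raise LeafSetError("unrooted completion requires trees with >= 3 leaves")
    l = min(T.leaf_labels())
    S_hat = root_at_leaf(S, l)
    T_hat = root_at_leaf(T, l)
    rooted = one_tree_completion(S_hat, T_hat)
    completed_u, umap = _unroot_with_map(rooted.completed)
    provenance = {
        umap[n]: p for n, p in rooted.provenance.items() if n in umap
    }
    return CompletionOne(
        completed=completed_u,
        rf=rf_distance(S, completed_u),
        provenance=provenance,
        grafts=rooted.grafts,
        rooting_leaf=l,
    )


# ---------------------------------------------------------------------------
# Extraneous clades / splits
# ---------------------------------------------------------------------------


def is_extraneous_clade(
    clade: Iterable[str], s_leaves: Iterable[str], t_leaves: Iterable[str]
) -> bool:
    """A clade is extraneous (w.r.t. original trees S and T) if it mixes
    leaves private to S with leaves private to T while containing no leaf
    shared by S and T."""
    c = frozenset(clade)
    s, t = frozenset(s_leaves), frozenset(t_leaves)
    if not c:
        raise LeafSetError("empty clade")
    return bool(c & (s - t)) and bool(c & (t - s)) and not (c & (s & t))


def find_extraneous(
    tree: RootedPhylo | UnrootedPhylo,
    s_leaves: Iterable[str],
    t_leaves: Iterable[str],
    rooting_leaf: str | None = None,
) -> list[frozenset[str]]:
    """All extraneous clades (rooted input) or the clades witnessing
    extraneous splits (unrooted input, judged after rooting at a common
    leaf). Empty list iff the tree is extraneous-free; for unrooted trees
    the verdict does not depend on which common leaf is used."""
    s, t = frozenset(s_leaves), frozenset(t_leaves)
    if isinstance(tree, RootedPhylo):
        clades = clade_set(tree)
    else:
        common = s & t
        if rooting_leaf is None:
            if not common:
                raise LeafSetError(
                    "no common leaf available to root the unrooted check"
                )
            rooting_leaf = min(common)
        elif rooting_leaf not in common:
            raise LeafSetError("rooting leaf must be common to both trees")
        clades = clade_set(root_at_leaf(tree, rooting_leaf))
    offending = [c for c in clades if is_extraneous_clade(c, s, t)]
    offending.sort(key=lambda c: (len(c), sorted(c)))
    return offending


# ---------------------------------------------------------------------------
# Two-tree completion (extraneous-free)
# ---------------------------------------------------------------------------


def two_tree_completion_ef(S: RootedPhylo, T: RootedPhylo) -> CompletionTwo:
    """Extraneous-clade-free completion of two rooted trees with partially
    overlapping leaf sets.

    Step 1 completes ``T`` on the union with respect to ``S`` (grafting the
    maximal subtrees of ``S`` holding S-private leaves); step 2 completes
    ``S`` with respect to that completion. The resulting pair contains no
    extraneous clades and minimizes the RF distance over all
    extraneous-clade-free completion pairs. With no shared leaves the
    problem has no solution and an error is raised.
    """
    if not isinstance(S, RootedPhylo) or not isinstance(T, RootedPhylo):
        raise PhyloError("two_tree_completion_ef expects rooted trees")
    if not (S.leaf_labels() & T.leaf_labels()):
        raise LeafSetError(
            "no extraneous-free completion exists: the trees share no leaves"
        )
    completed_t, prov_t, grafts_t = _graft_completion(S, T)
    completed_s, prov_s, grafts_s = _graft_completion(completed_t, S)
    return CompletionTwo(
        completed_s=completed_s,
        completed_t=completed_t,
        rf=rf_distance(completed_s, completed_t),
        provenance_s=prov_s,
        provenance_t=prov_t,
        grafts_s=grafts_s,
        grafts_t=grafts_t,
    )


def ef_u_completion(S: UnrootedPhylo, T: UnrootedPhylo) -> CompletionTwo:
    """Extraneous-split-free completion of two unrooted trees.

    Requires at least two shared leaves. Both trees are rooted on the edge
    of the lexicographically smallest shared leaf, completed with the
    rooted two-tree solver, and the roots are suppressed; the achieved RF
    value is independent of the rooting-leaf choice.
    """
    if not isinstance(S, UnrootedPhylo) or not isinstance(T, UnrootedPhylo):
        raise PhyloError("ef_u_completion expects unrooted trees")
    common = S.leaf_labels() & T.leaf_labels()
    if len(common) < 2:
        raise LeafSetError(
            "extraneous-split-free completion requires >= 2 shared leaves"
        )
    if S.n_leaves() < 3 or T.n_leaves() < 3:
        raise LeafSetError("unrooted completion requires trees with >= 3 leaves")
    l = min(common)
    rooted = two_tree_completion_ef(root_at_leaf(S, l), root_at_leaf(T, l))
    s_u, smap = _unroot_with_map(rooted.completed_s)
    t_u, tmap = _unroot_with_map(rooted.completed_t)
    return CompletionTwo(
        completed_s=s_u,
        completed_t=t_u,
        rf=rf_distance(s_u, t_u),
        provenance_s={smap[n]: p for n, p in rooted.provenance_s.items() if n in smap},
        provenance_t={tmap[n]: p for n, p in rooted.provenance_t.items() if n in tmap},
        grafts_s=rooted.grafts_s,
        grafts_t=rooted.grafts_t,
        rooting_leaf=l,
    )
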