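"""Synthetic instance generation and the RF(-)/RF(+) ranking experiment.

The generator emulates the inputs of the completion problems: a "true"
binary tree on a union leaf set is restricted to two overlapping subsets,
and topological discordance is optionally injected into the second tree by
random leaf prune-regraft moves. The ranking experiment orders a set of
input trees against a supertree by both the restriction-based RF(-)
distance and the completion-based RF(+) distance, and classifies every
pair of input trees by how the two rankings disagree:

* Type-1 — the strict orderings by RF(-) and RF(+) are opposite;
* Type-2 — RF(-) ties but RF(+) differs;
* Type-3 — RF(+) ties but RF(-) differs.

Pairs tied under both distances fall in none of the three types. The
classification logic is independent of how the supertree was obtained, so
any tree on a superset of the inputs' leaves may play that role (here,
typically the true tree itself).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .completion import one_tree_completion, uot_completion
from .tree_model import (
    LeafSetError,
    RNode,
    RootedPhylo,
    UnrootedPhylo,
    insert_leaf_unrooted,
    prune_leaf_unrooted,
    restrict,
    rf_distance,
)

__all__ = [
    "InstanceSpec",
    "PairClassification",
    "random_binary_tree",
    "make_instance",
    "leaf_prune_regraft",
    "rf_minus",
    "rf_plus",
    "classify_pairs",
    "rank_inputs",
]


@dataclass(frozen=True)
class InstanceSpec:
    """Parameters of one synthetic completion instance.

    ``n_union`` leaves carry labels ``t001..``; ``n_only_s``/``n_only_t``
    of them are private to S and T respectively; ``n_spr`` leaf
    prune-regraft moves perturb T after restriction; ``seed`` fixes all
    randomness. ``rooted`` selects the tree flavour.
    """

    n_union: int
    n_only_s: int = 0
    n_only_t: int = 0
    n_spr: int = 0
    seed: int = 0
    rooted: bool = True

    def __post_init__(self) -> None:
        if min(self.n_union, self.n_only_s, self.n_only_t, self.n_spr) < 0:
            raise ValueError("instance counts must be non-negative")
        if self.n_only_s + self.n_only_t >= self.n_union:
            raise ValueError("private leaves must not exhaust the union")


@dataclass(frozen=True)
class PairClassification:
    """Counts of ranking-discordant pairs among input trees."""

    n_trees: int
    type1: int
    type2: int
    type3: int
    total_pairs: int
    pct: float

    @classmethod
    def from_counts(
        cls, n_trees: int, type1: int, type2: int, type3: int
    ) -> "PairClassification":
        """Derive the pair total and the discordance percentage (2 decimals,
        half-up) from per-type counts."""
        total = n_trees * (n_trees - 1) // 2
        if type1 + type2 + type3 > total:
            raise ValueError("type counts exceed the number of pairs")
        pct_dec = (Decimal(100 * (type1 + type2 + type3)) / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
        return cls(
            n_trees=n_trees,
            type1=type1,
            type2=type2,
            type3=type3,
            total_pairs=total,
            pct=float(pct_dec),
        )


def _default_labels(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"t{i:0{width}d}" for i in range(1, n + 1)]


def random_binary_tree(
    labels: Sequence[str], seed: int, rooted: bool = True
) -> RootedPhylo | UnrootedPhylo:
    """Grow a uniformly attached binary tree by inserting ``labels`` in
    order, each at a uniformly random position (edge or, for rooted trees,
    above the root). Deterministic for a fixed (labels, seed)."""
    rng = random.Random(seed)
    return _random_tree(list(labels), rng, rooted)


def _random_tree(
    labels: list[str], rng: random.Random, rooted: bool
) -> RootedPhylo | UnrootedPhylo:
    from .completion import _tree_add_node

    if rooted:
        if len(labels) < 1:
            raise LeafSetError("rooted tree needs at least 1 leaf")
        tree = RootedPhylo(RNode(labels[0]))
        # positions list maintained incrementally: every node stands for its
        # parent edge, the root for the above-root position
        positions = [tree.root]
        for label in labels[1:]:
            leaf = RNode(label)
            new = _tree_add_node(tree, rng.choice(positions), leaf)
            positions.append(new)
            positions.append(leaf)
        return tree
    if len(labels) < 3:
        raise LeafSetError("unrooted tree needs at least 3 leaves")
    from .tree_model import UNode, _link

    center = UNode()
    for label in labels[:3]:
        _link(center, UNode(label))
    tree = UnrootedPhylo(center)
    edges = tree.edges()
    for label in labels[3:]:
        i = rng.randrange(len(edges))
        u, v = edges[i]
        leaf = insert_leaf_unrooted(tree, (u, v), label)
        mid = leaf.neighbors[0]
        edges[i] = (u, mid)
        edges.append((mid, v))
        edges.append((mid, leaf))
    return tree


def _insert_leaf_rooted_random(
    tree: RootedPhylo, label: str, rng: random.Random
) -> None:
    from .completion import _tree_add_node

    positions = list(tree.postorder())  # every node = its parent edge; root = above
    _tree_add_node(tree, rng.choice(positions), RNode(label))


def leaf_prune_regraft(
    tree: RootedPhylo | UnrootedPhylo, rng: random.Random
) -> None:
    """One discordance move: remove a uniformly chosen leaf (suppressing the
    vacated node) and re-insert it at a uniformly random position. In place.

    Kept deliberately simple — unlike a general SPR move it trivially
    preserves binarity.
    """
    if isinstance(tree, RootedPhylo):
        if tree.n_leaves() < 3:
            raise LeafSetError("prune-regraft needs >= 3 leaves")
        leaf = rng.choice(sorted(tree.leaves(), key=lambda n: n.label))
        label = leaf.label
        parent = leaf.parent
        sibling = next(c for c in parent.children if c is not leaf)
        grand = parent.parent
        if grand is None:
            sibling.parent = None
            tree.root = sibling
        else:
            grand.children[grand.children.index(parent)] = sibling
            sibling.parent = grand
        _insert_leaf_rooted_random(tree, label, rng)
    else:
        if tree.n_leaves() < 4:
            raise LeafSetError("unrooted prune-regraft needs >= 4 leaves")
        leaf = rng.choice(sorted(tree.leaves(), key=lambda n: n.label))
        label = leaf.label
        prune_leaf_unrooted(tree, leaf)
        insert_leaf_unrooted(tree, rng.choice(tree.edges()), label)


def make_instance(
    spec: InstanceSpec,
) -> tuple[RootedPhylo | UnrootedPhylo, RootedPhylo | UnrootedPhylo]:
    """Generate a completion instance (S, T) from a common base tree.

    S is the base restricted to the union minus the T-only leaves; T is the
    base restricted to the union minus the S-only leaves, perturbed by
    ``n_spr`` leaf prune-regraft moves. With ``n_spr=0`` and nested leaf
    sets the instance is conflict-free by construction.
    """
    rng = random.Random(spec.seed)
    labels = _default_labels(spec.n_union)
    base = _random_tree(list(labels), rng, spec.rooted)
    only_t = set(rng.sample(labels, spec.n_only_t))
    remaining = [l for l in labels if l not in only_t]
    only_s = set(rng.sample(remaining, spec.n_only_s))
    s_labels = [l for l in labels if l not in only_t]
    t_labels = [l for l in labels if l not in only_s]
    min_size = 1 if spec.rooted else 3
    if len(s_labels) < min_size or len(t_labels) < min_size:
        raise LeafSetError("restriction would fall below the minimum tree size")
    S = restrict(base, s_labels)
    T = restrict(base, t_labels)
    for _ in range(spec.n_spr):
        leaf_prune_regraft(T, rng)
    return S, T


def rf_minus(
    A: RootedPhylo | UnrootedPhylo, B: RootedPhylo | UnrootedPhylo
) -> int:
    """Restriction-based RF distance: restrict both trees to their common
    leaf set and compare."""
    common = A.leaf_labels() & B.leaf_labels()
    min_size = 1 if isinstance(A, RootedPhylo) else 3
    if len(common) < min_size:
        raise LeafSetError(
            f"common leaf set of size {len(common)} is too small for RF(-)"
        )
    return rf_distance(restrict(A, common), restrict(B, common))


def rf_plus(
    S: RootedPhylo | UnrootedPhylo, I: RootedPhylo | UnrootedPhylo
) -> int:
    """Completion-based RF distance of an input tree ``I`` to a supertree
    ``S`` (``Le(I) ⊆ Le(S)``): the RF distance achieved by an optimal
    completion of ``I`` on ``Le(S)``."""
    if isinstance(S, RootedPhylo):
        return one_tree_completion(S, I).rf
    return uot_completion(S, I).rf


def classify_pairs(
    supertree: RootedPhylo | UnrootedPhylo,
    inputs: Sequence[RootedPhylo | UnrootedPhylo],
) -> PairClassification:
    """Classify every unordered pair of input trees by the discordance of
    their RF(-) and RF(+) rankings against the supertree."""
    if len(inputs) < 2:
        raise LeafSetError("pair classification needs at least 2 input trees")
    super_leaves = supertree.leaf_labels()
    for tree in inputs:
        if not tree.leaf_labels() <= super_leaves:
            raise LeafSetError("input tree leaves must nest in the supertree's")
    minus = [rf_minus(supertree, t) for t in inputs]
    plus = [rf_plus(supertree, t) for t in inputs]
    t1 = t2 = t3 = 0
    n = len(inputs)
    for i in range(n):
        for j in range(i + 1, n):
            dm = minus[i] - minus[j]
            dp = plus[i] - plus[j]
            if dm and dp and (dm > 0) != (dp > 0):
                t1 += 1
            elif dm == 0 and dp != 0:
                t2 += 1
            elif dp == 0 and dm != 0:
                t3 += 1
    return PairClassification.from_counts(n, t1, t2, t3)


def rank_inputs(
    supertree: RootedPhylo | UnrootedPhylo,
    inputs: Sequence[RootedPhylo | UnrootedPhylo],
) -> tuple[list[dict], PairClassification]:
    """Per-tree RF(-)/RF(+) table plus the pair classification."""
    rows = [
        {
            "tree": i,
            "n_leaves": t.n_leaves(),
            "rf_minus": rf_minus(supertree, t),
            "rf_plus": rf_plus(supertree, t),
        }
        for i, t in enumerate(inputs)
    ]
    return rows, classify_pairs(supertree, inputs)
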