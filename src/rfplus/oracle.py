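"""Exhaustive reference solvers for small completion instances.

These enumerate every completion (or every pair of completions) of a tree
by inserting the missing leaves sequentially at every possible position,
and minimize the RF distance directly. They are deliberately simple and
obviously correct, and exist solely to verify the optimality of the
linear-time solvers on small instances; hard size guards prevent
accidental exponential runs.
"""

from __future__ import annotations

import random
from typing import Iterator, Literal, Sequence

from .completion import find_extraneous, tree_add
from .tree_model import (
    LeafSetError,
    PhyloError,
    RNode,
    RootedPhylo,
    UnrootedPhylo,
    clade_set,
    insert_leaf_unrooted,
    rf_distance,
    split_set,
)

__all__ = [
    "SizeGuardError",
    "enumerate_completions",
    "enumerate_completions_unrooted",
    "brute_one_tree",
    "brute_two_tree",
    "brute_unrooted",
    "random_guarded_instances",
    "cross_validate",
]

#: Largest total leaf count accepted by the single-tree enumerators.
MAX_ONE_TREE_LEAVES = 12
#: Largest union leaf count accepted by the pair enumerators.
MAX_TWO_TREE_LEAVES = 10


class SizeGuardError(PhyloError):
    """Instance exceeds the oracle's hard size guard."""


def _check_extra(tree, extra: Sequence[str], guard: int) -> None:
    base = tree.leaf_labels()
    if base & set(extra):
        raise LeafSetError("extra leaves collide with existing labels")
    if len(set(extra)) != len(extra):
        raise LeafSetError("duplicate labels among extra leaves")
    if len(base) + len(extra) > guard:
        raise SizeGuardError(
            f"{len(base) + len(extra)} leaves exceeds the oracle guard of {guard}"
        )


def enumerate_completions(
    T: RootedPhylo, extra: Sequence[str]
) -> Iterator[RootedPhylo]:
    """Yield every rooted completion of ``T`` with the leaves in ``extra``.

    Leaves are inserted sequentially; each insertion considers every edge
    plus the above-root position (2m-1 positions on an m-leaf tree). Every
    completion topology is emitted at least once; duplicates may occur and
    are tolerated (minimization is unaffected).
    """
    _check_extra(T, extra, MAX_ONE_TREE_LEAVES)
    if not extra:
        yield T.copy()[0]
        return
    label, rest = extra[0], extra[1:]
    positions = list(T.postorder())  # non-root nodes = parent edges; root = above-root
    for node in positions:
        Tc, nmap = T.copy()
        tree_add(Tc, nmap[node], RootedPhylo(RNode(label)))
        yield from enumerate_completions(Tc, rest)


def enumerate_completions_unrooted(
    T: UnrootedPhylo, extra: Sequence[str]
) -> Iterator[UnrootedPhylo]:
    """Unrooted analog of :func:`enumerate_completions`: each insertion
    considers every edge (2m-3 positions on an m-leaf tree)."""
    _check_extra(T, extra, MAX_ONE_TREE_LEAVES)
    if not extra:
        yield T.copy()[0]
        return
    label, rest = extra[0], extra[1:]
    for u, v in T.edges():
        Tc, nmap = T.copy()
        insert_leaf_unrooted(Tc, (nmap[u], nmap[v]), label)
        yield from enumerate_completions_unrooted(Tc, rest)


def brute_one_tree(
    S: RootedPhylo, T: RootedPhylo
) -> tuple[int, RootedPhylo]:
    """Exact minimum of RF(S, T') over all rooted completions T' of T on
    Le(S), with one argmin completion."""
    if not T.leaf_labels() <= S.leaf_labels():
        raise LeafSetError("Le(T) must be a subset of Le(S)")
    extra = sorted(S.leaf_labels() - T.leaf_labels())
    best_rf: int | None = None
    best_tree: RootedPhylo | None = None
    clades_s = clade_set(S)
    for cand in enumerate_completions(T, extra):
        clades_c = clade_set(cand)
        rf = len(clades_s) + len(clades_c) - 2 * len(clades_s & clades_c)
        if best_rf is None or rf < best_rf:
            best_rf, best_tree = rf, cand
    return best_rf, best_tree


def _distinct_completions_rooted(
    base: RootedPhylo, extra: Sequence[str], ef_filter: tuple | None
) -> list[frozenset[frozenset[str]]]:
    """Clade sets of the distinct completions of ``base``; with
    ``ef_filter=(s_leaves, t_leaves)`` only extraneous-clade-free ones."""
    out: dict[frozenset[frozenset[str]], None] = {}
    for cand in enumerate_completions(base, extra):
        key = clade_set(cand)
        if key in out:
            continue
        if ef_filter is not None and find_extraneous(cand, *ef_filter):
            continue
        out[key] = None
    return list(out)


def brute_two_tree(S: RootedPhylo, T: RootedPhylo, ef_only: bool) -> int:
    """Exact minimum of RF(S', T') over all pairs of rooted completions of
    S and T on the union leaf set; with ``ef_only`` the pairs in which
    either tree has an extraneous clade are excluded."""
    ls, lt = S.leaf_labels(), T.leaf_labels()
    union = ls | lt
    if len(union) > MAX_TWO_TREE_LEAVES:
        raise SizeGuardError(
            f"{len(union)} union leaves exceeds the pair-oracle guard of "
            f"{MAX_TWO_TREE_LEAVES}"
        )
    if ef_only and not (ls & lt):
        raise LeafSetError(
            "no extraneous-free completion pair exists for disjoint leaf sets"
        )
    ef = (ls, lt) if ef_only else None
    cands_s = _distinct_completions_rooted(S, sorted(lt - ls), ef)
    cands_t = _distinct_completions_rooted(T, sorted(ls - lt), ef)
    best: int | None = None
    for cs in cands_s:
        for ct in cands_t:
            rf = len(cs) + len(ct) - 2 * len(cs & ct)
            if best is None or rf < best:
                best = rf
    return best


def brute_unrooted(
    S: UnrootedPhylo,
    T: UnrootedPhylo,
    mode: Literal["one-tree", "ef-two-tree"],
) -> int:
    """Exact unrooted minima: ``mode="one-tree"`` minimizes RF(S, T') over
    unrooted completions of T on Le(S) (requires Le(T) ⊆ Le(S));
    ``mode="ef-two-tree"`` minimizes RF(S', T') over extraneous-split-free
    completion pairs on the union leaf set."""
    ls, lt = S.leaf_labels(), T.leaf_labels()
    if mode == "one-tree":
        if not lt <= ls:
            raise LeafSetError("Le(T) must be a subset of Le(S)")
        extra = sorted(ls - lt)
        splits_s = split_set(S)
        best: int | None = None
        for cand in enumerate_completions_unrooted(T, extra):
            sp = split_set(cand)
            rf = len(splits_s) + len(sp) - 2 * len(splits_s & sp)
            if best is None or rf < best:
                best = rf
        return best
    if mode != "ef-two-tree":
        raise ValueError(f"unknown mode {mode!r}")
    union = ls | lt
    if len(union) > MAX_TWO_TREE_LEAVES:
        raise SizeGuardError(
            f"{len(union)} union leaves exceeds the pair-oracle guard of "
            f"{MAX_TWO_TREE_LEAVES}"
        )
    if len(ls & lt) < 2:
        raise LeafSetError("ef-two-tree mode requires >= 2 shared leaves")

    def distinct(base: UnrootedPhylo, extra: Sequence[str]):
        out: dict[frozenset[frozenset[str]], None] = {}
        for cand in enumerate_completions_unrooted(base, extra):
            key = split_set(cand)
            if key in out:
                continue
            if find_extraneous(cand, ls, lt):
                continue
            out[key] = None
        return list(out)

    cands_s = distinct(S, sorted(lt - ls))
    cands_t = distinct(T, sorted(ls - lt))
    best = None
    for cs in cands_s:
        for ct in cands_t:
            rf = len(cs) + len(ct) - 2 * len(cs & ct)
            if best is None or rf < best:
                best = rf
    return best


# ---------------------------------------------------------------------------
# Randomized cross-validation sweeps
# ---------------------------------------------------------------------------

#: Problems accepted by :func:`cross_validate`.
Problem = Literal["rot", "uot", "ef-r", "ef-u"]


def random_guarded_instances(
    problem: Problem, n_instances: int, seed: int
):
    """Yield ``n_instances`` random (S, T) pairs within the oracle's size
    guards for the given completion problem.

    Instance sizes: one-tree problems draw 4-7 union leaves with 1-3
    missing; two-tree problems draw 5-8 union leaves with 1-2 private
    leaves per side; up to 3 leaf prune-regraft moves inject discordance
    whenever the perturbed tree is large enough to admit them.
    """
    from .simulate import InstanceSpec, make_instance

    rng = random.Random(seed)
    produced = 0
    while produced < n_instances:
        if problem == "rot":
            n = rng.randint(4, 7)
            miss = rng.randint(1, min(3, n - 1))
            spec = InstanceSpec(
                n_union=n, n_only_s=miss, n_only_t=0,
                n_spr=rng.randint(0, 3) if n - miss >= 3 else 0,
                seed=rng.randrange(2**30), rooted=True,
            )
        elif problem == "uot":
            n = rng.randint(5, 7)
            miss = rng.randint(1, min(3, n - 3))
            spec = InstanceSpec(
                n_union=n, n_only_s=miss, n_only_t=0,
                n_spr=rng.randint(0, 3) if n - miss >= 4 else 0,
                seed=rng.randrange(2**30), rooted=False,
            )
        elif problem == "ef-r":
            n = rng.randint(5, 8)
            a, b = rng.randint(1, 2), rng.randint(1, 2)
            spec = InstanceSpec(
                n_union=n, n_only_s=a, n_only_t=b,
                n_spr=rng.randint(0, 3) if n - a >= 3 else 0,
                seed=rng.randrange(2**30), rooted=True,
            )
        elif problem == "ef-u":
            n = rng.randint(6, 8)
            a, b = rng.randint(1, 2), rng.randint(1, 2)
            if n - a < 4 or n - b < 3:
                continue
            spec = InstanceSpec(
                n_union=n, n_only_s=a, n_only_t=b,
                n_spr=rng.randint(0, 2),
                seed=rng.randrange(2**30), rooted=False,
            )
        else:
            raise ValueError(f"unknown problem {problem!r}")
        S, T = make_instance(spec)
        if problem == "ef-u" and len(S.leaf_labels() & T.leaf_labels()) < 2:
            continue
        produced += 1
        yield S, T


def cross_validate(problem: Problem, n_instances: int, seed: int) -> tuple[int, int]:
    """Compare the linear-time solver with the exhaustive oracle on random
    guarded instances; returns (number agreeing, number run).

    Any disagreement is an optimality failure of the solver (or the
    oracle), so the expected result is ``(n, n)``.
    """
    from .completion import (
        ef_u_completion,
        one_tree_completion,
        two_tree_completion_ef,
        uot_completion,
    )

    agree = 0
    for S, T in random_guarded_instances(problem, n_instances, seed):
        if problem == "rot":
            got = one_tree_completion(S, T).rf
            expected, _ = brute_one_tree(S, T)
        elif problem == "uot":
            got = uot_completion(S, T).rf
            expected = brute_unrooted(S, T, "one-tree")
        elif problem == "ef-r":
            got = two_tree_completion_ef(S, T).rf
            expected = brute_two_tree(S, T, ef_only=True)
        else:
            got = ef_u_completion(S, T).rf
            expected = brute_unrooted(S, T, "ef-two-tree")
        if got == expected:
            agree += 1
    return agree, n_instances
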