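"""Completion solvers: coloring, LCA mapping, grafting and optimality."""

import random

import pytest

from rfplus import (
    Color,
    LeafSetError,
    Provenance,
    RootedPhylo,
    brute_one_tree,
    color_and_mark,
    ef_u_completion,
    find_extraneous,
    is_extraneous_clade,
    lca_build,
    lca_mapping,
    one_tree_completion,
    random_binary_tree,
    random_guarded_instances,
    restrict,
    rf_distance,
    root_at_leaf,
    tree_add,
    trees_equal,
    two_tree_completion_ef,
    uot_completion,
    write_newick,
)
from rfplus.tree_model import RNode
from helpers import rooted, unrooted


def _labels(n):
    return [f"t{i:02d}" for i in range(n)]


def _maximal_red_subtrees(S, shared):
    """Leaf sets of the maximal all-missing subtrees of S, computed
    independently of the solver's marking machinery."""
    coloring = color_and_mark(S, shared)
    out = []
    for node in S.preorder():
        if coloring.color[node] is Color.RED and (
            node is S.root or coloring.color[node.parent] is not Color.RED
        ):
            out.append(frozenset(n.label for n in RootedPhylo(node).leaves()))
    return out


class TestColoring:
    def test_single_marked_root(self):
        S = rooted("((a,b),(c,d));")
        col = color_and_mark(S, {"a", "b"})
        by_label = {n.label: n for n in S.leaves()}
        assert col.color[by_label["a"]] is Color.GREEN
        assert col.color[by_label["c"]] is Color.RED
        assert col.color[by_label["a"].parent] is Color.GREEN
        assert col.color[by_label["c"].parent] is Color.RED
        assert col.color[S.root] is Color.BLUE
        assert col.marked == {S.root}

    def test_full_overlap_all_green(self):
        S = rooted("((a,b),(c,d));")
        col = color_and_mark(S, S.leaf_labels())
        assert set(col.color.values()) == {Color.GREEN}
        assert not col.marked

    def test_two_marked_cherries(self):
        S = rooted("((a,c),(b,d));")
        col = color_and_mark(S, {"a", "b"})
        by_label = {n.label: n for n in S.leaves()}
        assert col.marked == {by_label["a"].parent, by_label["b"].parent}
        assert col.color[S.root] is Color.BLUE

    def test_rejects_bad_reference_set(self):
        S = rooted("(a,b);")
        with pytest.raises(LeafSetError):
            color_and_mark(S, set())
        with pytest.raises(LeafSetError):
            color_and_mark(S, {"z"})

    @pytest.mark.parametrize("seed", range(10))
    def test_no_blue_node_has_two_red_children(self, seed):
        rng = random.Random(seed)
        n = rng.randint(4, 14)
        S = random_binary_tree(_labels(n), seed=rng.randrange(2**30), rooted=True)
        shared = set(rng.sample(_labels(n), rng.randint(1, n - 1)))
        col = color_and_mark(S, shared)
        for node in S.postorder():
            if node.is_leaf or col.color[node] is not Color.BLUE:
                continue
            reds = sum(1 for c in node.children if col.color[c] is Color.RED)
            assert reds <= 1
            assert (node in col.marked) == (reds == 1)


class TestLcaMapping:
    def test_maps_to_target_root(self):
        S, T = rooted("((a,b),(c,d));"), rooted("(a,b);")
        col = color_and_mark(S, T.leaf_labels())
        M = lca_mapping(S, col, T, lca_build(T))
        by_label = {n.label: n for n in S.leaves()}
        assert M[S.root] is T.root
        assert M[by_label["a"].parent] is T.root

    def test_green_leaves_map_to_like_labeled_leaves(self):
        S, T = rooted("((a,b),(c,d));"), rooted("((a,b),c);")
        col = color_and_mark(S, T.leaf_labels())
        M = lca_mapping(S, col, T, lca_build(T))
        tmap = T.label_map()
        for leaf in S.leaves():
            if leaf.label in tmap:
                assert M[leaf] is tmap[leaf.label]

    def test_maps_through_single_non_red_child(self):
        S, T = rooted("((a,c),(b,d));"), rooted("(a,b);")
        col = color_and_mark(S, T.leaf_labels())
        M = lca_mapping(S, col, T, lca_build(T))
        by_label = {n.label: n for n in S.leaves()}
        tmap = T.label_map()
        assert M[by_label["a"].parent] is tmap["a"]
        assert M[by_label["b"].parent] is tmap["b"]
        assert M[S.root] is T.root


class TestTreeAdd:
    def test_graft_on_leaf_edge(self):
        T = rooted("(a,b);")
        tree_add(T, T.label_map()["a"], rooted("c;"))
        assert trees_equal(T, rooted("((a,c),b);"))

    def test_graft_above_root(self):
        T = rooted("(a,b);")
        tree_add(T, T.root, rooted("c;"))
        assert trees_equal(T, rooted("((a,b),c);"))

    def test_graft_subtree(self):
        T = rooted("(a,b);")
        tree_add(T, T.label_map()["b"], rooted("(c,d);"))
        assert trees_equal(T, rooted("(a,(b,(c,d)));"))

    def test_rejects_label_collision_and_foreign_node(self):
        T = rooted("(a,b);")
        with pytest.raises(LeafSetError):
            tree_add(T, T.root, rooted("(a,c);"))
        other = rooted("(x,y);")
        with pytest.raises(Exception):
            tree_add(T, other.root, rooted("c;"))


class TestOneTreeCompletion:
    @pytest.mark.parametrize(
        "s_text,t_text,expected,expected_rf",
        [
            ("((a,b),(c,d));", "(a,b);", "((a,b),(c,d));", 0),
            ("((a,b),(c,d));", "((a,c),b);", "((a,(c,d)),b);", 2),
            ("((a,c),(b,d));", "(a,b);", "((a,c),(b,d));", 0),
        ],
    )
    def test_worked_examples(self, s_text, t_text, expected, expected_rf):
        S, T = rooted(s_text), rooted(t_text)
        res = one_tree_completion(S, T)
        assert res.rf == expected_rf
        assert trees_equal(res.completed, rooted(expected))
        assert res.rf == brute_one_tree(S, T)[0]

    def test_equal_leaf_sets_returns_t_unchanged(self):
        S, T = rooted("((a,b),(c,d));"), rooted("((a,c),(b,d));")
        res = one_tree_completion(S, T)
        assert trees_equal(res.completed, T)
        assert res.rf == rf_distance(S, T)
        assert res.n_grafts == 0

    def test_single_leaf_target(self):
        S = rooted("((a,b),(c,d));")
        res = one_tree_completion(S, rooted("c;"))
        assert res.rf == 0
        assert trees_equal(res.completed, S)

    def test_rejects_non_nested_leaf_sets(self):
        with pytest.raises(LeafSetError):
            one_tree_completion(rooted("(a,b);"), rooted("(a,z);"))

    @pytest.mark.parametrize("seed", range(8))
    def test_validity_and_provenance(self, seed):
        (S, T), = random_guarded_instances("rot", 1, seed)
        res = one_tree_completion(S, T)
        # a completion restricts back to the input tree
        assert trees_equal(restrict(res.completed, T.leaf_labels()), T)
        # every grafted subtree is a maximal all-missing subtree of the donor
        expected_grafts = _maximal_red_subtrees(S, S.leaf_labels() & T.leaf_labels())
        assert sorted(map(sorted, res.grafts)) == sorted(map(sorted, expected_grafts))
        # provenance partitions the internal nodes
        internals = [n for n in res.completed.postorder() if not n.is_leaf]
        assert set(res.provenance) == set(internals)
        assert res.rf == rf_distance(S, res.completed)
        kinds = set(res.provenance.values())
        assert kinds <= {Provenance.ORIGINAL, Provenance.GRAFTED, Provenance.COPIED_RED}


class TestUnrootedOneTree:
    def test_star_completion(self):
        S, T = unrooted("((a,b),(c,d));"), unrooted("(a,b,c);")
        res = uot_completion(S, T)
        assert res.rf == 0
        assert trees_equal(res.completed, S)

    def test_equal_leaf_sets(self):
        S, T = unrooted("((a,b),(c,d));"), unrooted("((a,c),(b,d));")
        res = uot_completion(S, T)
        assert trees_equal(res.completed, T)
        assert res.rf == rf_distance(S, T)

    def test_caterpillar_completion(self):
        # S has splits ab|cde and abc|de
        S = unrooted("((a,b),c,(d,e));")
        res = uot_completion(S, unrooted("(a,b,c);"))
        assert res.rf == 0
        assert trees_equal(res.completed, S)

    def test_rejects_degenerate_sizes(self):
        with pytest.raises(Exception):
            uot_completion(unrooted("(a,b,c);"), rooted("(a,b);"))

    @pytest.mark.parametrize("seed", range(6))
    def test_rf_value_invariant_to_rooting_leaf(self, seed):
        (S, T), = random_guarded_instances("uot", 1, 50 + seed)
        res = uot_completion(S, T)
        for label in sorted(T.leaf_labels()):
            rooted_run = one_tree_completion(
                root_at_leaf(S, label), root_at_leaf(T, label)
            )
            assert rooted_run.rf == res.rf


class TestExtraneous:
    def test_definition(self):
        s_only, t_only = {"c", "d"}, {"i", "j"}
        common = {"a", "b"}
        s_leaves, t_leaves = common | s_only, common | t_only
        assert is_extraneous_clade({"c", "i"}, s_leaves, t_leaves)
        assert not is_extraneous_clade({"a", "c", "i"}, s_leaves, t_leaves)
        assert not is_extraneous_clade({"c", "d"}, s_leaves, t_leaves)

    def test_detects_planted_extraneous_clade(self):
        tree = rooted("((a,(c,i)),b);")
        got = find_extraneous(tree, {"a", "b", "c"}, {"a", "b", "i"})
        assert got == [frozenset({"c", "i"})]

    def test_all_common_leaves_is_always_clean(self):
        tree = rooted("((a,b),c);")
        assert find_extraneous(tree, {"a", "b", "c"}, {"a", "b", "c"}) == []

    def test_unrooted_verdict_independent_of_rooting_leaf(self):
        tree = unrooted("(((c,i),a),b,d);")
        s_leaves, t_leaves = {"a", "b", "c", "d"}, {"a", "b", "d", "i"}
        verdicts = {
            tuple(sorted(map(tuple, map(sorted, find_extraneous(
                tree, s_leaves, t_leaves, rooting_leaf=l)))))
            for l in ("a", "b", "d")
        }
        assert len(verdicts) == 1
        assert verdicts.pop() == (("c", "i"),)


class TestTwoTreeCompletion:
    def test_nested_private_leaves(self):
        S, T = rooted("((a,c),b);"), rooted("((a,i),b);")
        res = two_tree_completion_ef(S, T)
        expected = rooted("(((a,c),i),b);")
        assert res.rf == 0
        assert trees_equal(res.completed_s, expected)
        assert trees_equal(res.completed_t, expected)

    def test_equal_leaf_sets(self):
        S, T = rooted("((a,b),c);"), rooted("((a,c),b);")
        res = two_tree_completion_ef(S, T)
        assert trees_equal(res.completed_s, S)
        assert trees_equal(res.completed_t, T)
        assert res.rf == rf_distance(S, T)

    def test_conflicting_placements(self):
        S, T = rooted("((a,b),(c,x));"), rooted("((a,c),(b,y));")
        res = two_tree_completion_ef(S, T)
        assert res.rf == 2
        assert trees_equal(res.completed_s, rooted("((a,(b,y)),(c,x));"))
        assert trees_equal(res.completed_t, rooted("((a,(c,x)),(b,y));"))

    def test_disjoint_leaf_sets_have_no_solution(self):
        with pytest.raises(LeafSetError):
            two_tree_completion_ef(rooted("(a,b);"), rooted("(x,y);"))

    @pytest.mark.parametrize("seed", range(8))
    def test_outputs_are_valid_and_extraneous_free(self, seed):
        (S, T), = random_guarded_instances("ef-r", 1, 200 + seed)
        res = two_tree_completion_ef(S, T)
        ls, lt = S.leaf_labels(), T.leaf_labels()
        assert trees_equal(restrict(res.completed_s, ls), S)
        assert trees_equal(restrict(res.completed_t, lt), T)
        assert find_extraneous(res.completed_s, ls, lt) == []
        assert find_extraneous(res.completed_t, ls, lt) == []
        # grafted subtrees are the maximal all-missing subtrees of the donors
        assert sorted(map(sorted, res.grafts_t)) == sorted(
            map(sorted, _maximal_red_subtrees(S, ls & lt))
        )


class TestUnrootedTwoTree:
    def test_matches_rooted_optimum_on_shared_instance(self):
        # unrooted version of the conflicting-placement instance, padded
        # with an extra shared leaf to satisfy the degree constraints
        S = unrooted("(((a,b),(c,x)),e,f);")
        T = unrooted("(((a,c),(b,y)),e,f);")
        res = ef_u_completion(S, T)
        l = min(S.leaf_labels() & T.leaf_labels())
        rooted_res = two_tree_completion_ef(root_at_leaf(S, l), root_at_leaf(T, l))
        assert res.rf == rooted_res.rf

    def test_equal_leaf_sets(self):
        S, T = unrooted("((a,b),(c,d));"), unrooted("((a,c),(b,d));")
        res = ef_u_completion(S, T)
        assert trees_equal(res.completed_s, S)
        assert trees_equal(res.completed_t, T)
        assert res.rf == rf_distance(S, T)

    def test_rejects_overlap_below_two(self):
        with pytest.raises(LeafSetError):
            ef_u_completion(unrooted("(a,x,y);"), unrooted("(a,u,v);"))

    @pytest.mark.parametrize("seed", range(6))
    def test_outputs_extraneous_free_and_leaf_invariant(self, seed):
        (S, T), = random_guarded_instances("ef-u", 1, 300 + seed)
        res = ef_u_completion(S, T)
        ls, lt = S.leaf_labels(), T.leaf_labels()
        assert find_extraneous(res.completed_s, ls, lt) == []
        assert find_extraneous(res.completed_t, ls, lt) == []
        assert trees_equal(restrict(res.completed_s, ls), S)
        assert trees_equal(restrict(res.completed_t, lt), T)
        for label in sorted(ls & lt):
            alt = two_tree_completion_ef(root_at_leaf(S, label), root_at_leaf(T, label))
            assert alt.rf == res.rf
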