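"""Islands, pairing, LRF/RF distances, edit operations and edit paths."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from lrfdist import (
    Del,
    Ins,
    InvalidEditError,
    Sub,
    UNLABELED,
    apply_edit,
    apply_edit_path,
    compare_trees,
    edit_path,
    island_lrf,
    labeled_isomorphic,
    lrf_distance,
    parse_tree,
    perturb,
    prepare_pair,
    random_labeled_tree,
    rf_distance,
)
from lrfdist.lrf_core import Island, extract_islands, pair_islands, _run_pipeline
from lrfdist.oracle import lrf_oracle, rf_oracle
from lrfdist.tree_model import _prepare_single
from conftest import make_pair


def _island(epsilon, labels):
    return Island(
        nodes=tuple(range(epsilon + 1)),
        top=0,
        anchor="ROOT",
        labels=frozenset(labels),
        terminal_leaves=frozenset(),
        child_anchors=frozenset(),
    )


class TestIslands:
    def test_worked_example_has_four_island_pairs(self, worked_pair):
        report = compare_trees(*worked_pair)
        assert len(report.pairing.pairs) == 4

    def test_identical_trees_give_one_star_island_per_internal_node(self):
        t = parse_tree("(((A,B)x,(C,D)y)z,(E,F)w)r;")
        pipe = _run_pipeline(t, t.copy())
        islands = pipe.pairing.pairs
        assert len(islands) == len(t.internal_nodes())
        assert all(p.island1.epsilon == 0 for p in islands)
        assert pipe.pairing.delta == 0

    def test_star_partner_gives_single_island(self):
        t1 = parse_tree("((((A,B)x,C)x,D)x,E)x;", rooted=True)
        t2 = parse_tree("(A,B,C,D,E)x;", rooted=True)
        pipe = _run_pipeline(t1, t2)
        assert len(pipe.pairing.pairs) == 1
        pair = pipe.pairing.pairs[0]
        assert pair.island1.epsilon == 3 and pair.island2.epsilon == 0

    def test_bad_edges_partition_into_islands(self, rng):
        for _ in range(50):
            t1, t2 = make_pair(rng)
            pipe = _run_pipeline(t1, t2)
            isl1 = [p.island1 for p in pipe.pairing.pairs]
            isl2 = [p.island2 for p in pipe.pairing.pairs]
            # every internal node in exactly one island core
            for tree, islands in ((pipe.p1, isl1), (pipe.p2, isl2)):
                seen = [u for isl in islands for u in isl.nodes]
                assert sorted(seen) == tree.internal_nodes()
            # island counts agree between the trees (the pairing bijection)
            assert len(isl1) == len(isl2)

    def test_mismatched_island_lists_raise(self):
        a, b = _island(0, {"x"}), _island(1, {"y"})
        with pytest.raises(AssertionError):
            pair_islands([a], [a, b])


class TestIslandLRF:
    def test_shared_label_costs_epsilons_only(self):
        assert island_lrf((_island(2, {"dup"}), _island(1, {"dup", "spec"}))) == 3

    def test_label_disjoint_star_pair_costs_one_substitution(self):
        assert island_lrf((_island(0, {"dup"}), _island(0, {"spec"}))) == 1

    def test_label_disjoint_pair_verified_by_search(self):
        """6-leaf pair, eps=2 and eps'=2 on disjoint labels: 5 edits exactly."""
        t1 = parse_tree(
            "((((A,B)speciation,C)speciation,D)speciation,(E,F)speciation)speciation;"
        )
        t2 = parse_tree(
            "((((A,D)duplication,C)duplication,B)duplication,(E,F)speciation)speciation;"
        )
        pipe = _run_pipeline(t1, t2)
        big = [p for p in pipe.pairing.pairs if p.island1.epsilon == 2]
        assert len(big) == 1 and big[0].island2.epsilon == 2
        assert not big[0].shares_label
        assert big[0].lrf == 5
        assert lrf_distance(t1, t2) == 5 == lrf_oracle(t1, t2, max_cost=7)


class TestDistances:
    def test_identity(self, worked_pair):
        t1, _ = worked_pair
        assert lrf_distance(t1, t1.copy()) == 0

    def test_single_label_change_costs_one(self):
        t1 = parse_tree("((A,B)speciation,(C,D)speciation)speciation;")
        t2 = parse_tree("((A,B)duplication,(C,D)speciation)speciation;")
        assert lrf_distance(t1, t2) == 1
        assert rf_distance(t1, t2) == 0

    def test_all_labels_foreign_delta_counts_every_island(self):
        t1 = parse_tree("((A,B)speciation,(C,D)speciation)speciation;")
        t2 = parse_tree("((A,B)duplication,(C,D)duplication)duplication;")
        report = compare_trees(t1, t2)
        # identical topologies: one star island per internal node (+ dummy side)
        assert report.delta == len(report.pairing.pairs)
        assert report.lrf == report.delta

    def test_worked_example_distance(self, worked_pair):
        report = compare_trees(*worked_pair)
        assert (report.lrf, report.rf, report.delta) == (7, 5, 2)
        assert sorted(p.lrf for p in report.pairing.pairs) == [0, 0, 1, 6]

    def test_rf_unrooted_quartet_swap(self):
        t1 = parse_tree("(A,B,(C,D)y)z;")
        t2 = parse_tree("(A,C,(B,D)y)z;")
        assert rf_distance(t1, t2) == 2 == rf_oracle(t1, t2)

    def test_rf_binary_vs_star(self):
        t1 = parse_tree("((A,B)x,C,D)z;")
        t2 = parse_tree("(A,B,C,D)x;", rooted=False)
        assert rf_distance(t1, t2) == 1 == rf_oracle(t1, t2)

    def test_unlabeled_mode_reduces_to_rf(self, rng):
        for _ in range(25):
            t1, t2 = make_pair(rng, n_labels=1)
            assert set(t1.label.values()) == {"speciation"}
            report = compare_trees(t1, t2)
            u1, u2 = t1.copy(), t2.copy()
            for u in u1.internal_nodes():
                u1.set_label(u, UNLABELED)
            for u in u2.internal_nodes():
                u2.set_label(u, UNLABELED)
            assert lrf_distance(u1, u2) == report.rf


class TestApplyEdit:
    def test_deletion_then_inverse_insertion_restores(self):
        t = parse_tree("(((A,B)x,C)y,(D,E)z)r;")
        pipe_tree = _prepare_single(t)
        # contract the edge above the cherry (A,B): its node merges into y
        x = next(
            u
            for u in pipe_tree.internal_nodes()
            if {pipe_tree.leaf_name.get(c) for c in pipe_tree.neighbors(u)}
            >= {"A", "B"}
        )
        y = next(c for c in pipe_tree.neighbors(x) if not pipe_tree.is_leaf(c))
        moved = frozenset(c for c in pipe_tree.neighbors(x) if c != y)
        after = apply_edit(pipe_tree, Del(x=x, y=y))
        back = apply_edit(after, Ins(y=y, moved=moved, label="x", new_id=x))
        assert labeled_isomorphic(back, pipe_tree)

    def test_substitution_is_an_involution(self):
        t = parse_tree("((A,B)speciation,C)speciation;")
        node = t.internal_nodes()[0]
        once = apply_edit(t, Sub(x=node, label="duplication"))
        twice = apply_edit(once, Sub(x=node, label="speciation"))
        assert labeled_isomorphic(t, twice)
        assert not labeled_isomorphic(t, once)

    def test_insertion_on_degree_four_node_moves_rf_by_one(self):
        t = parse_tree("(A,B,C,D,E)x;", rooted=False)
        p = _prepare_single(t)
        y = p.internal_nodes()[0]
        moved = frozenset(
            u for u in p.sorted_neighbors(y) if p.leaf_name.get(u) in ("B", "C")
        )
        after = apply_edit(p, Ins(y=y, moved=moved, label="x"))
        assert rf_oracle(p, after) == 1

    def test_degree_constraints_enforced(self):
        t = parse_tree("((A,B)x,C)y;")
        p = _prepare_single(t)
        # Ins needs degree >= 4
        with pytest.raises(InvalidEditError):
            apply_edit(p, Ins(y=p.internal_nodes()[0], moved=frozenset(), label="x"))
        # Del needs an internal neighbor
        leafy = p.internal_nodes()[0]
        leaf_nb = next(c for c in p.neighbors(leafy) if p.is_leaf(c))
        with pytest.raises(InvalidEditError):
            apply_edit(p, Del(x=leafy, y=leaf_nb))

    def test_moved_set_bounds(self):
        t = parse_tree("(A,B,C,D,E)x;", rooted=False)
        p = _prepare_single(t)
        y = p.internal_nodes()[0]
        nbrs = p.sorted_neighbors(y)
        with pytest.raises(InvalidEditError):
            apply_edit(p, Ins(y=y, moved=frozenset(nbrs[:1]), label="x"))
        with pytest.raises(InvalidEditError):
            apply_edit(p, Ins(y=y, moved=frozenset(nbrs[:4]), label="x"))


class TestEditPath:
    def test_identical_trees_empty_path(self, worked_pair):
        t1, _ = worked_pair
        assert edit_path(t1, t1.copy()) == []

    def test_label_disjoint_star_pair_single_substitution(self):
        t1 = parse_tree("(A,B,C,D)speciation;", rooted=True)
        t2 = parse_tree("(A,B,C,D)duplication;", rooted=True)
        ops = edit_path(t1, t2)
        assert len(ops) == 1 and isinstance(ops[0], Sub)

    def test_path_length_equals_distance_and_replay_reaches_target(self, rng):
        for _ in range(40):
            t1, t2 = make_pair(rng, n_min=4, n_max=12, n_labels=rng.choice([1, 2, 3]))
            ops = edit_path(t1, t2)
            assert len(ops) == lrf_distance(t1, t2)
            result = apply_edit_path(t1, ops)
            assert labeled_isomorphic(result, _prepare_single(t2))

    def test_path_is_deterministic(self, worked_pair):
        assert edit_path(*worked_pair) == edit_path(*worked_pair)


class TestMetricProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**30))
    def test_symmetry_exact(self, seed):
        t1, t2 = make_pair(random.Random(seed), n_max=20)
        assert lrf_distance(t1, t2) == lrf_distance(t2, t1)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**30))
    def test_triangle_inequality(self, seed):
        rng = random.Random(seed)
        n = rng.randint(4, 15)
        a, b, c = (
            random_labeled_tree(n, seed=rng.randrange(2**30), shape="binary")
            for _ in range(3)
        )
        assert lrf_distance(a, c) <= lrf_distance(a, b) + lrf_distance(b, c)

    def test_decomposition_identity(self, rng):
        """LRF = RF + delta with RF confirmed by the bipartition oracle."""
        for _ in range(30):
            t1, t2 = make_pair(rng)
            report = compare_trees(t1, t2)
            assert report.lrf == report.rf + report.delta
            assert report.rf == rf_oracle(t1, t2)

    def test_perturbation_never_exceeds_edit_count(self):
        t = random_labeled_tree(30, seed=5)
        for k in (1, 3, 7, 15):
            edited, ops = perturb(t, k, seed=k)
            assert len(ops) == k
            assert lrf_distance(t, edited) <= k


class TestReport:
    def test_json_schema(self, worked_pair):
        report = compare_trees(*worked_pair)
        d = report.to_dict()
        assert set(d) == {"lrf", "rf", "delta", "islands"}
        for isl in d["islands"]:
            assert set(isl) == {
                "epsilon_t1",
                "epsilon_t2",
                "labels_t1",
                "labels_t2",
                "label_disjoint",
                "lrf",
                "terminal_leaves_t1",
                "terminal_leaves_t2",
            }
        assert d["lrf"] == sum(i["lrf"] for i in d["islands"])
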