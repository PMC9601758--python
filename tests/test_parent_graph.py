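"""Sparse parent graph construction and bitvector best-parent queries."""

import pytest

import bndp as b
from bndp.constraints import ConstraintSet, EdgeConstraint, PathConstraint
from bndp.core import Dag, decode_subset, descendant_masks, encode_subset, iter_bits
from bndp.parent_graph import (
    InfeasibleQueryError,
    SparseParentGraph,
    _membership,
    build_spg_edge,
    build_spg_path,
    build_spg_unconstrained,
    query_best_parents_edge,
    query_best_parents_path,
)
from bndp.scoring import random_score_table

from conftest import random_truth


def _spg_from_lists(child, n, sets, scores, mode="edge"):
    masks = [encode_subset(s, n) for s in sets]
    return SparseParentGraph(child, n, masks, scores, _membership(masks, n), mode)


@pytest.fixture
def worked_edge_spg():
    """Five candidate parent sets of X3 with scores 5..1 (descending)."""
    return _spg_from_lists(
        2, 5, [[0, 4], [0, 1, 3], [0, 1, 4], [], [0]], [5, 4, 3, 2, 1]
    )


@pytest.fixture
def worked_path_instance():
    """Tail child Y with candidates over X1..X4 and the substructure
    X1->X3, X2->X4, X4->X3 providing the descendant sets."""
    spg = _spg_from_lists(4, 5, [[1, 3], [3], [2, 3], [], [2]], [5, 4, 3, 2, 1], "full")
    g_u = Dag(5, [0, 0, encode_subset([0, 3], 5), encode_subset([1], 5), 0])
    c = ConstraintSet(
        5,
        paths=[PathConstraint(0, 4, "required"), PathConstraint(1, 4, "required")],
    )
    return spg, g_u, c


class TestWorkedExamples:
    def test_edge_query_with_required_and_forbidden(self, worked_edge_spg):
        u = encode_subset([0, 1, 3, 4], 5)
        mask, score, valid = query_best_parents_edge(
            2, u, encode_subset([0, 1], 5), encode_subset([3], 5),
            worked_edge_spg, return_valid=True,
        )
        assert decode_subset(mask) == [0, 1, 4] and score == 3
        assert [int((valid >> t) & 1) for t in range(5)] == [0, 0, 1, 0, 0]

    def test_edge_query_unconstrained(self, worked_edge_spg):
        u = encode_subset([0, 1, 3, 4], 5)
        mask, score = query_best_parents_edge(2, u, 0, 0, worked_edge_spg)
        assert decode_subset(mask) == [0, 4] and score == 5

    def test_path_query_with_required_ancestors(self, worked_path_instance):
        spg, g_u, c = worked_path_instance
        u = encode_subset([0, 1, 2, 3], 5)
        mask, score, valid = query_best_parents_path(
            4, u, c, spg, g_u, return_valid=True
        )
        assert decode_subset(mask) == [2, 3] and score == 3
        assert [int((valid >> t) & 1) for t in range(5)] == [0, 0, 1, 0, 1]

    def test_path_query_unconstrained(self, worked_path_instance):
        spg, g_u, _ = worked_path_instance
        u = encode_subset([0, 1, 2, 3], 5)
        mask, score = query_best_parents_path(4, u, ConstraintSet(5), spg, g_u)
        assert decode_subset(mask) == [1, 3] and score == 5


class TestUnconstrainedBuild:
    def test_empty_set_always_stored(self, rng):
        cache = random_score_table(4, 2, rng)
        spg = build_spg_unconstrained(cache, 0)
        assert 0 in spg.parent_masks

    def test_single_candidate_parent(self):
        from bndp.scoring import LocalScoreTable

        cache = LocalScoreTable(2, 1, [{0: -1.0, 0b10: -0.5}, {0: -1.0, 0b01: -2.0}])
        keep = build_spg_unconstrained(cache, 0)
        drop = build_spg_unconstrained(cache, 1)
        assert set(keep.parent_masks) == {0, 0b10}  # {X2} beats {}
        assert set(drop.parent_masks) == {0}  # {X1} dominated by {}

    def test_scores_sorted_with_mask_tiebreak(self, rng):
        cache = random_score_table(5, 2, rng)
        spg = build_spg_unconstrained(cache, 1)
        order = list(zip([-s for s in spg.scores], spg.parent_masks))
        assert order == sorted(order)

    def test_top_stored_subset_attains_brute_max(self, rng):
        """For every pool U, the first stored set inside U has the best
        cached score among all parent sets inside U."""
        for trial in range(10):
            n = 5
            cache = random_score_table(n, 3, rng)
            child = trial % n
            spg = build_spg_unconstrained(cache, child)
            for u in range(1 << n):
                u &= ~(1 << child)
                best = max(
                    (s for m, s in cache.candidates(child).items() if m & ~u == 0),
                )
                got = max(
                    (s for m, s in zip(spg.parent_masks, spg.scores) if m & ~u == 0),
                )
                assert got == pytest.approx(best)

    def test_membership_rebuild_is_bit_exact(self, rng):
        cache = random_score_table(6, 2, rng)
        spg = build_spg_unconstrained(cache, 3)
        assert spg.rebuild_membership() == spg.membership


class TestEdgeBuild:
    def test_forbidden_parent_never_stored(self, rng):
        cache = random_score_table(5, 3, rng)
        c = ConstraintSet(
            5,
            edges=[EdgeConstraint(0, 2, "required"), EdgeConstraint(3, 2, "forbidden")],
        )
        spg = build_spg_edge(cache, 2, c)
        assert all(not m & 0b01000 for m in spg.parent_masks)

    def test_required_set_always_stored(self, rng):
        cache = random_score_table(5, 3, rng)
        c = ConstraintSet(5, edges=[EdgeConstraint(0, 2, "required")])
        spg = build_spg_edge(cache, 2, c)
        assert 0b00001 in spg.parent_masks

    def test_query_equals_brute_force_constrained_max(self, rng):
        for trial in range(25):
            n = int(rng.integers(3, 7))
            child = int(rng.integers(n))
            others = [v for v in range(n) if v != child]
            rng.shuffle(others)
            required = encode_subset(others[:1], n) if rng.random() < 0.7 else 0
            forbidden = encode_subset(others[1:2], n) if rng.random() < 0.7 else 0
            c = ConstraintSet(
                n,
                edges=[EdgeConstraint(p, child, "required") for p in iter_bits(required)]
                + [EdgeConstraint(p, child, "forbidden") for p in iter_bits(forbidden)],
            )
            cache = random_score_table(n, int(rng.integers(1, n)), rng)
            spg = build_spg_edge(cache, child, c)
            u = (int(rng.integers(0, 1 << n)) | required) & ~(1 << child)
            admissible = [
                (s, m)
                for m, s in cache.candidates(child).items()
                if m & ~u == 0 and required & ~m == 0 and not m & forbidden
            ]
            if not admissible:
                with pytest.raises(InfeasibleQueryError):
                    query_best_parents_edge(child, u, required, forbidden, spg)
                continue
            mask, score = query_best_parents_edge(child, u, required, forbidden, spg)
            assert score == pytest.approx(max(admissible)[0])

    def test_constrained_never_beats_unconstrained(self, rng):
        cache = random_score_table(5, 2, rng)
        c = ConstraintSet(5, edges=[EdgeConstraint(0, 2, "required")])
        spg_c = build_spg_edge(cache, 2, c)
        spg_u = build_spg_unconstrained(cache, 2)
        u = encode_subset([0, 1, 3, 4], 5)
        _, s_con = query_best_parents_edge(2, u, 0b1, 0, spg_c)
        _, s_unc = query_best_parents_edge(2, u, 0, 0, spg_u)
        assert s_con <= s_unc + 1e-12


class TestPathBuild:
    def test_tail_child_gets_full_table(self, rng):
        cache = random_score_table(5, 2, rng)
        c = ConstraintSet(5, paths=[PathConstraint(0, 2, "required")])
        spg = build_spg_path(cache, 2, c)
        assert spg.mode == "full" and spg.size == 1 + 4 + 6

    def test_non_tail_identical_to_unconstrained(self, rng):
        cache = random_score_table(5, 2, rng)
        c = ConstraintSet(5, paths=[PathConstraint(0, 2, "required")])
        spg = build_spg_path(cache, 1, c)
        ref = build_spg_unconstrained(cache, 1)
        assert (spg.parent_masks, spg.scores, spg.membership) == (
            ref.parent_masks, ref.scores, ref.membership,
        )

    def test_query_equals_linear_scan(self, rng):
        """Path query agrees with an explicit set-logic scan over the table."""
        for _ in range(25):
            n = int(rng.integers(4, 7))
            child = int(rng.integers(n))
            g_u = random_truth(n, rng)
            others = [v for v in range(n) if v != child]
            rng.shuffle(others)
            req, forb = others[:1], others[1:2]
            c = ConstraintSet(
                n,
                paths=[PathConstraint(a, child, "required") for a in req]
                + [PathConstraint(a, child, "forbidden") for a in forb],
            )
            cache = random_score_table(n, 2, rng)
            spg = build_spg_path(cache, child, c)
            u = ((1 << n) - 1) & ~(1 << child)
            des = descendant_masks(g_u)
            groups_req = [(des[a] | (1 << a)) & u for a in req]
            groups_forb = [(des[a] | (1 << a)) & u for a in forb]
            admissible = [
                (s, m)
                for m, s in zip(spg.parent_masks, spg.scores)
                if m & ~u == 0
                and all(m & g for g in groups_req)
                and not any(m & g for g in groups_forb)
            ]
            if not admissible:
                with pytest.raises(InfeasibleQueryError):
                    query_best_parents_path(child, u, c, spg, g_u)
                continue
            mask, score = query_best_parents_path(child, u, c, spg, g_u)
            assert score == pytest.approx(max(admissible)[0])

    def test_required_ancestor_outside_pool_rejected(self, worked_path_instance):
        spg, g_u, c = worked_path_instance
        with pytest.raises(ValueError):
            query_best_parents_path(4, encode_subset([1, 2, 3], 5), c, spg, g_u)
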