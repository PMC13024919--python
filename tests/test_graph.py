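"""Chordal graph / clique tree machinery."""

import numpy as np
import pytest

from copulagm.graph import (
    CliqueTree,
    Move,
    UndirectedGraph,
    apply_move,
    build_clique_tree,
    is_chordal,
    maximal_cliques,
    valid_deletions,
    valid_insertions,
)

from conftest import brute_force_moves, random_chordal_walk


def G_of(d, edges):
    return UndirectedGraph(d, set(edges))


C4 = [(0, 1), (1, 2), (2, 3), (0, 3)]
TRIANGLE = [(0, 1), (1, 2), (0, 2)]


@pytest.mark.parametrize("d,edges,expected", [
    (4, C4, False),                      # chordless 4-cycle
    (3, TRIANGLE, True),                 # complete graphs are chordal
    (5, [], True),                       # no cycles at all
    (4, C4 + [(1, 3)], True),            # chord restores chordality
])
def test_is_chordal(d, edges, expected):
    assert is_chordal(G_of(d, edges)) is expected


@pytest.mark.parametrize("d,edges,cliques", [
    (3, [(0, 1), (1, 2)], [{0, 1}, {1, 2}]),
    (3, TRIANGLE, [{0, 1, 2}]),
    (4, C4 + [(1, 3)], [{0, 1, 3}, {1, 2, 3}]),
    (5, [], [{0}, {1}, {2}, {3}, {4}]),
])
def test_maximal_cliques(d, edges, cliques):
    got = maximal_cliques(G_of(d, edges))
    assert sorted(map(sorted, got)) == sorted(map(sorted, cliques))
    # brute-force maximality: no clique contained in another
    for a in got:
        assert not any(a < b for b in got)


def test_maximal_cliques_strict_mode_rejects_non_chordal():
    with pytest.raises(ValueError):
        maximal_cliques(G_of(4, C4), strict=True)


class TestBuildCliqueTree:
    def test_path_graph(self):
        T = build_clique_tree(G_of(3, [(0, 1), (1, 2)]))
        assert sorted(map(sorted, T.cliques.values())) == [[0, 1], [1, 2]]
        assert list(T.separator_multiset().items()) == [(frozenset({1}), 1)]

    def test_single_clique(self):
        T = build_clique_tree(G_of(3, TRIANGLE))
        assert len(T.cliques) == 1
        assert T.separator_multiset() == {}

    def test_disconnected_edges_form_forest(self):
        T = build_clique_tree(G_of(4, [(0, 1), (2, 3)]))
        assert len(T.cliques) == 2
        assert T.tree_edges() == []  # forest: empty-separator components apart
        T.validate()

    def test_rejects_non_chordal(self):
        with pytest.raises(ValueError):
            build_clique_tree(G_of(4, C4))

    def test_clique_count_bounded_by_d(self):
        for seed in range(5):
            G, T = random_chordal_walk(7, 25, seed)
            assert len(T.cliques) <= G.d
            T.validate()


class TestValidMoves:
    def test_triangle_deletions(self):
        G = G_of(3, TRIANGLE)
        moves = valid_deletions(G, build_clique_tree(G))
        assert {(m.i, m.j) for m in moves} == {(0, 1), (1, 2), (0, 2)}
        for m in moves:
            assert m.separator == frozenset({0, 1, 2}) - {m.i, m.j}

    def test_chord_not_deletable(self):
        G = G_of(4, C4 + [(1, 3)])
        moves = valid_deletions(G, build_clique_tree(G))
        assert {m.edge for m in moves} == set(C4)

    def test_single_edge_deletable_with_empty_separator(self):
        G = G_of(2, [(0, 1)])
        (m,) = valid_deletions(G, build_clique_tree(G))
        assert m.separator == frozenset()

    def test_path_insertion_separator(self):
        G = G_of(3, [(0, 1), (1, 2)])
        moves = valid_insertions(G, build_clique_tree(G))
        assert [(m.edge, set(m.separator)) for m in moves] == [((0, 2), {1})]

    def test_longer_path_excludes_chordless_cycle(self):
        G = G_of(4, [(0, 1), (1, 2), (2, 3)])
        moves = valid_insertions(G, build_clique_tree(G))
        got = {m.edge: m.separator for m in moves}
        assert (0, 3) not in got  # would create a chordless C4
        assert got[(0, 2)] == frozenset({1})
        assert got[(1, 3)] == frozenset({2})

    def test_empty_graph_all_insertions_valid(self):
        d = 5
        G = UndirectedGraph(d)
        moves = valid_insertions(G, build_clique_tree(G))
        assert len(moves) == d * (d - 1) // 2
        assert all(m.separator == frozenset() for m in moves)


class TestApplyMove:
    def assert_matches_rebuild(self, T, G_after):
        R = build_clique_tree(G_after)
        assert T.canonical() == R.canonical()

    def test_insert_absorbs_both_cliques(self):
        G = G_of(3, [(0, 1), (1, 2)])
        T = build_clique_tree(G)
        (m,) = valid_insertions(G, T)
        apply_move(T, m)
        assert list(T.cliques.values()) == [frozenset({0, 1, 2})]
        assert T.separator_multiset() == {}

    def test_delete_splits_clique(self):
        G = G_of(3, TRIANGLE)
        T = build_clique_tree(G)
        move = next(m for m in valid_deletions(G, T) if m.edge == (0, 2))
        apply_move(T, move)
        assert sorted(map(sorted, T.cliques.values())) == [[0, 1], [1, 2]]
        assert T.separator_multiset() == {frozenset({1}): 1}

    def test_delete_with_neighbor_clique(self):
        G = G_of(4, [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3)])
        T = build_clique_tree(G)
        move = next(m for m in valid_deletions(G, T) if m.edge == (0, 1))
        apply_move(T, move)
        assert sorted(map(sorted, T.cliques.values())) == [[0, 2], [1, 2, 3]]
        assert T.separator_multiset() == {frozenset({2}): 1}

    def test_invalid_move_raises(self):
        G = G_of(4, C4 + [(1, 3)])
        T = build_clique_tree(G)
        with pytest.raises(ValueError):
            apply_move(T, Move("delete", 1, 3, frozenset()))


@pytest.mark.parametrize("d,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (7, 4)])
def test_moves_match_brute_force_oracle_along_random_walks(d, seed):
    """Tree-criterion admissibility == edit-then-check chordality, and the
    incremental tree update == rebuild from scratch, along random walks."""

    def check(G, T, move):
        ins, dels = brute_force_moves(G)
        got_ins = valid_insertions(G, T)
        got_del = valid_deletions(G, T)
        assert {m.edge for m in got_ins} == ins
        assert {m.edge for m in got_del} == dels
        # separators: the unique maximal clique of G+/-e containing {i,j}
        for m in got_ins:
            H = G.copy()
            H.add_edge(m.i, m.j)
            holders = [K for K in maximal_cliques(H) if {m.i, m.j} <= K]
            assert len(holders) == 1
            assert m.separator == holders[0] - {m.i, m.j}

    G, T = random_chordal_walk(d, 30, seed, check=check)
    assert is_chordal(G)
    T.validate()
    assert T.canonical() == build_clique_tree(G).canonical()
    assert T.graph() == G


def test_apply_move_equals_rebuild_each_step():
    for seed in range(4):
        def check(G, T, move):
            H = G.copy()
            if move.kind == "insert":
                H.add_edge(move.i, move.j)
            else:
                H.remove_edge(move.i, move.j)
            import copy
            T2 = copy.deepcopy(T)
            apply_move(T2, move)
            assert T2.canonical() == build_clique_tree(H).canonical()
            T2.validate()

        random_chordal_walk(6, 25, 100 + seed, check=check)
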