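import numpy as np
import pytest

from copulagm.graph import (
    UndirectedGraph,
    apply_move,
    build_clique_tree,
    is_chordal,
    valid_deletions,
    valid_insertions,
)


def brute_force_moves(G: UndirectedGraph):
    """Oracle: edits whose result stays chordal, found by edit-then-check."""
    ins, dels = set(), set()
    for (i, j) in G.non_edges():
        H = G.copy()
        H.add_edge(i, j)
        if is_chordal(H):
            ins.add((i, j))
    for (i, j) in sorted(G.edges):
        H = G.copy()
        H.remove_edge(i, j)
        if is_chordal(H):
            dels.add((i, j))
    return ins, dels


def random_chordal_walk(d: int, steps: int, seed: int, check=None):
    """Random walk over chordal graphs via valid moves, from the empty graph.

    ``check(G, T, move)`` is called before each applied move; the walk keeps
    the tree incrementally via apply_move.
    """
    rng = np.random.default_rng(seed)
    G = UndirectedGraph(d)
    T = build_clique_tree(G)
    for _ in range(steps):
        moves = valid_insertions(G, T) + valid_deletions(G, T)
        if not moves:
            break
        move = moves[rng.integers(len(moves))]
        if check is not None:
            check(G, T, move)
        apply_move(T, move)
        if move.kind == "insert":
            G.add_edge(move.i, move.j)
        else:
            G.remove_edge(move.i, move.j)
    return G, T


@pytest.fixture
def gaussian_copula_pair():
    """Factory: n samples from a bivariate Gaussian copula with corr r."""

    def make(r: float, n: int, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        cov = np.array([[1.0, r], [r, 1.0]])
        return rng.multivariate_normal([0.0, 0.0], cov, size=n)

    return make
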