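"""Greedy chordality-preserving structure search and the sklearn estimator.

Starting from the empty graph, each iteration enumerates every admissible
single-edge insertion and deletion (admissibility = the edited graph stays
chordal, checked on the maintained clique tree), scores each candidate by
its four-term local delta, and applies the move with the largest strictly
positive improvement.  The search stops at the first iteration with no
improving admissible move — a local optimum of the score over decomposable
graphs.

Determinism: ties between equal-delta moves are broken by preferring
insertions over deletions and then by lexicographic edge order; with fixed
data, fold seed and configuration the whole move sequence is reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .copent import CopulaEntropyEstimator, EstimatorConfig, RawKDEEstimator
from .graph import (
    CliqueTree,
    Move,
    UndirectedGraph,
    apply_move,
    build_clique_tree,
    is_chordal,
    valid_deletions,
    valid_insertions,
)
from .scoring import GraphScorer, ScoreCache, ScoreConfig, make_scorer

logger = logging.getLogger(__name__)


@dataclass
class TraceRecord:
    """One accepted move of the greedy search."""

    iteration: int
    kind: str
    i: int
    j: int
    sep_size: int
    delta: float
    score: float
    n_cliques: int
    max_clique: int


@dataclass
class SearchConfig:
    max_iter: Optional[int] = None  # default: d*(d-1), a generous safety cap
    debug_checks: bool = False  # re-verify chordality/tree every iteration


def _move_sort_key(move: Move, delta: float) -> Tuple:
    return (-delta, 0 if move.kind == "insert" else 1, move.i, move.j)


def greedy_search(scorer: GraphScorer, d: int,
                  config: Optional[SearchConfig] = None,
                  ) -> Tuple[UndirectedGraph, CliqueTree, List[TraceRecord]]:
    """Run the greedy forward/backward search with a prepared scorer."""
    config = config or SearchConfig()
    G = UndirectedGraph(d)
    T = build_clique_tree(G)
    score = scorer.global_score(T)
    if not np.isfinite(score):
        warnings.warn("empty-graph score is not finite; returning empty graph")
        return G, T, []
    trace: List[TraceRecord] = []
    max_iter = config.max_iter if config.max_iter is not None else d * (d - 1)
    any_finite_ever = False
    for it in range(max_iter):
        best: Optional[Tuple[Tuple, Move, float]] = None
        candidates = valid_insertions(G, T) + valid_deletions(G, T)
        for move in candidates:
            delta = scorer.delta(move)
            if not np.isfinite(delta):
                # inadmissible this iteration (numerical failure); it may be
                # retried after the state changes
                continue
            any_finite_ever = True
            if delta > 0.0:
                key = _move_sort_key(move, delta)
                if best is None or key < best[0]:
                    best = (key, move, delta)
        if best is None:
            break
        _, move, delta = best
        apply_move(T, move)
        if move.kind == "insert":
            G.add_edge(move.i, move.j)
        else:
            G.remove_edge(move.i, move.j)
        score += delta
        if config.debug_checks:
            assert is_chordal(G), "search left the chordal class"
            T.validate()
            assert T.graph() == G, "clique tree out of sync with graph"
        trace.append(TraceRecord(
            iteration=it, kind=move.kind, i=move.i, j=move.j,
            sep_size=len(move.separator), delta=delta, score=score,
            n_cliques=len(T.cliques),
            max_clique=max(len(K) for K in T.cliques.values()),
        ))
        logger.info(
            "iter %d: %s (%d,%d) delta=%.4f score=%.4f",
            it, move.kind, move.i, move.j, delta, score,
        )
    if not trace and not any_finite_ever:
        warnings.warn("no finite score could be computed; returning empty graph")
    return G, T, trace


class DecomposableGraphLearner(BaseEstimator):
    """Greedy structure learner for continuous decomposable Markov fields.

    Fits a chordal undirected dependence graph to an ``(n, d)`` data matrix
    by maximising either the copula-information score with a BIC-type
    penalty (``score="cbic"``, rank-invariant) or an out-of-fold predictive
    log-likelihood of clique/separator kernel densities (``score="ng_ll"``,
    the unpenalised raw-scale baseline).

    Parameters
    ----------
    score : "cbic" or "ng_ll".
    penalty : complexity formula for cbic, "quadratic" ``|A|(|A|+1)/2``
        (default) or "linear" ``|A|``.
    k_folds, epsilon, density_floor, beta_min, beta_max,
    optimizer_max_iter, optimizer_rel_tol : estimator hyperparameters, see
        :class:`copulagm.copent.EstimatorConfig`.
    max_iter : cap on greedy iterations (default ``d*(d-1)``).
    random_state : seed for the fold assignment.

    Attributes
    ----------
    graph_ : learned :class:`UndirectedGraph`.
    clique_tree_ : maintained :class:`CliqueTree` of ``graph_``.
    trace_ : list of :class:`TraceRecord`, one per accepted move.
    score_ : final global score value.
    bandwidth_ : selected global kernel variances (one per column).
    n_features_in_ : number of columns seen during fit.

    Examples
    --------
    >>> from copulagm.simulate import BenchmarkSpec, sample_dataset
    >>> data = sample_dataset(BenchmarkSpec(d=6, n=400, seed=3))
    >>> learner = DecomposableGraphLearner().fit(data.X["normal"])
    >>> sorted(learner.graph_.edges)  # doctest: +SKIP
    """

    def __init__(self, score: str = "cbic", penalty: str = "quadratic",
                 k_folds: int = 5, epsilon: float = 1e-5,
                 density_floor: float = 1e-100, beta_min: float = 1.0,
                 beta_max: Optional[float] = None,
                 optimizer_max_iter: int = 200,
                 optimizer_rel_tol: float = 1e-8,
                 max_iter: Optional[int] = None,
                 debug_checks: bool = False,
                 random_state: int = 0) -> None:
        self.score = score
        self.penalty = penalty
        self.k_folds = k_folds
        self.epsilon = epsilon
        self.density_floor = density_floor
        self.beta_min = beta_min
        self.beta_max = beta_max
        self.optimizer_max_iter = optimizer_max_iter
        self.optimizer_rel_tol = optimizer_rel_tol
        self.max_iter = max_iter
        self.debug_checks = debug_checks
        self.random_state = random_state

    def _estimator_config(self) -> EstimatorConfig:
        return EstimatorConfig(
            k_folds=self.k_folds, epsilon=self.epsilon,
            density_floor=self.density_floor, beta_min=self.beta_min,
            beta_max=self.beta_max, max_iter=self.optimizer_max_iter,
            rel_tol=self.optimizer_rel_tol,
            seed=int(self.random_state or 0),
        )

    def fit(self, X, y=None) -> "DecomposableGraphLearner":
        X = check_array(X, ensure_min_samples=3, ensure_min_features=2)
        est_config = self._estimator_config()
        if self.score == "cbic":
            psi_est = CopulaEntropyEstimator(X, est_config)
        elif self.score == "ng_ll":
            psi_est = RawKDEEstimator(X, est_config)
        else:
            raise ValueError(f"unknown score {self.score!r}")
        scorer = make_scorer(psi_est, kind=self.score, penalty=self.penalty)
        self.psi_estimator_ = psi_est
        self.bandwidth_ = psi_est.bandwidth.theta
        search_config = SearchConfig(
            max_iter=self.max_iter, debug_checks=self.debug_checks,
        )
        self.graph_, self.clique_tree_, self.trace_ = greedy_search(
            scorer, X.shape[1], search_config,
        )
        self.scorer_ = scorer
        self.score_ = scorer.global_score(self.clique_tree_)
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def adjacency_(self) -> np.ndarray:
        check_is_fitted(self, "graph_")
        A = np.zeros((self.n_features_in_, self.n_features_in_), dtype=int)
        for (i, j) in self.graph_.edges:
            A[i, j] = A[j, i] = 1
        return A


def greedy_learn(X, score: str = "cbic",
                 est_config: Optional[EstimatorConfig] = None,
                 penalty: str = "quadratic",
                 max_iter: Optional[int] = None,
                 ) -> Tuple[UndirectedGraph, CliqueTree, List[TraceRecord]]:
    """Functional wrapper over :class:`DecomposableGraphLearner`."""
    est_config = est_config or EstimatorConfig()
    learner = DecomposableGraphLearner(
        score=score, penalty=penalty, k_folds=est_config.k_folds,
        epsilon=est_config.epsilon, density_floor=est_config.density_floor,
        beta_min=est_config.beta_min, beta_max=est_config.beta_max,
        optimizer_max_iter=est_config.max_iter,
        optimizer_rel_tol=est_config.rel_tol, max_iter=max_iter,
        random_state=est_config.seed,
    ).fit(X)
    return learner.graph_, learner.clique_tree_, learner.trace_
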