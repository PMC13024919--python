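"""Synthetic chordal Gaussian-copula benchmark generator.

The generator produces datasets with a *known* decomposable dependence
structure while letting the one-dimensional marginals vary:

1. draw an Erdős–Rényi graph ``G0 ~ G(d, rho)`` and triangulate it
   (minimum-degree fill-in) into a chordal ground truth ``G``;
2. give each edge an independent Gamma(shape=2, rate=1) weight, assemble
   the ridge-regularised graph Laplacian ``Q = nu*I + D - W`` (strictly
   diagonally dominant, hence positive definite, with off-diagonal zeros
   exactly on the non-edges of ``G``) and standardise its inverse to a
   correlation matrix ``R``;
3. sample latent Gaussians ``Z ~ N(0, R)``, map to the copula scale
   ``U = Phi(Z)``, and push ``U`` through the quantile function of each
   marginal family: Normal(0,1) (so ``X = Z`` exactly), Exponential(1) and
   Beta(1/2, 1/2).

All three marginal datasets share the same ``U`` and hence identical
within-column ranks — only the marginal shape differs, which is exactly the
perturbation a rank-invariant score must ignore.

Random-number stream order is fixed (graph edges, then edge weights, then
latent normals), so one seed reproduces a dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.special import ndtr
from scipy.stats import beta as beta_dist

from .graph import UndirectedGraph, is_chordal

MARGINAL_FAMILIES = ("normal", "exponential", "beta")


@dataclass
class BenchmarkSpec:
    """Parameters of one synthetic benchmark draw.

    ``nu`` is the ridge added to the graph Laplacian; it is the main knob
    for signal strength (larger ``nu`` weakens all latent correlations).
    Gamma weights use shape ``alpha=2`` and *rate* ``beta=1`` (mean 2).
    """

    d: int = 30
    rho: float = 0.1
    n: int = 2000
    nu: float = 1.0
    gamma_shape: float = 2.0
    gamma_rate: float = 1.0
    marginals: Sequence[str] = MARGINAL_FAMILIES
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0, 1)")
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.n < 2:
            raise ValueError("need n >= 2")
        unknown = set(self.marginals) - set(MARGINAL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown marginal families {unknown}")


@dataclass
class SyntheticDataset:
    """One benchmark draw: truth graph, latent quantities and datasets."""

    truth: UndirectedGraph
    X: Dict[str, np.ndarray]
    U: np.ndarray
    Z: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    SQS: np.ndarray
    spec: BenchmarkSpec


def _erdos_renyi(d: int, rho: float, rng: np.random.Generator) -> UndirectedGraph:
    G = UndirectedGraph(d)
    for i in range(d):
        for j in range(i + 1, d):
            if rng.random() < rho:
                G.add_edge(i, j)
    return G


def triangulate(G: UndirectedGraph) -> UndirectedGraph:
    """Chordal completion via the minimum-degree elimination heuristic.

    Repeatedly eliminates a vertex of minimum remaining degree (ties broken
    by smallest label), connecting its remaining neighbours; the fill edges
    are added to a copy of ``G``.  Deterministic, and a no-op on graphs that
    are already chordal up to the heuristic's fill.
    """
    adj = {v: G.neighbors(v) for v in range(G.d)}
    out = G.copy()
    remaining = set(range(G.d))
    while remaining:
        v = min(remaining, key=lambda u: (len(adj[u] & remaining), u))
        nbrs = sorted(adj[v] & remaining)
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                x, y = nbrs[a], nbrs[b]
                if y not in adj[x]:
                    adj[x].add(y)
                    adj[y].add(x)
                    out.add_edge(x, y)
        remaining.remove(v)
    assert is_chordal(out)
    return out


def sample_chordal_truth(d: int, rho: float,
                         seed_or_rng) -> UndirectedGraph:
    """Chordal ground truth: Erdős–Rényi draw followed by triangulation."""
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    return triangulate(_erdos_renyi(d, rho, rng))


def build_correlation(G: UndirectedGraph, nu: float, seed_or_rng,
                      gamma_shape: float = 2.0, gamma_rate: float = 1.0,
                      ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision, correlation and standardised precision for a truth graph.

    Gamma weights are drawn for every vertex pair (in lexicographic order,
    keeping the RNG stream independent of the edge set) and masked by the
    edge indicator; ``Q = nu*I + D - W`` is the ridge-regularised Laplacian,
    ``R`` the correlation matrix of ``Q^{-1}`` and ``SQS = R^{-1}`` the
    standardised precision, whose off-diagonal zero pattern equals the
    non-edges of ``G``.
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    d = G.d
    W = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            y = rng.gamma(shape=gamma_shape, scale=1.0 / gamma_rate)
            if (i, j) in G.edges:
                W[i, j] = W[j, i] = y
    Q = nu * np.eye(d) + np.diag(W.sum(axis=1)) - W
    cov = np.linalg.inv(Q)
    s = np.sqrt(np.diag(cov))
    R = cov / np.outer(s, s)
    SQS = Q * np.outer(s, s)
    return Q, R, SQS


def marginal_ppf(u: np.ndarray, family: str) -> np.ndarray:
    """Quantile transform of copula-scale data for one marginal family."""
    from scipy.special import ndtri
    if family == "normal":
        return ndtri(u)
    if family == "exponential":
        return -np.log1p(-u)
    if family == "beta":
        return beta_dist.ppf(u, 0.5, 0.5)
    raise ValueError(f"unknown marginal family {family!r}")


def sample_dataset(spec: BenchmarkSpec) -> SyntheticDataset:
    """Draw one full benchmark dataset from a :class:`BenchmarkSpec`."""
    rng = np.random.default_rng(spec.seed)
    truth = sample_chordal_truth(spec.d, spec.rho, rng)
    Q, R, SQS = build_correlation(
        truth, spec.nu, rng, spec.gamma_shape, spec.gamma_rate,
    )
    Z = rng.multivariate_normal(
        np.zeros(spec.d), R, size=spec.n, method="cholesky",
    )
    U = ndtr(Z)
    X: Dict[str, np.ndarray] = {}
    for family in spec.marginals:
        # the Normal(0,1) family is exactly the latent Z (Phi^{-1}(Phi(Z)))
        X[family] = Z.copy() if family == "normal" else marginal_ppf(U, family)
    return SyntheticDataset(truth=truth, X=X, U=U, Z=Z, Q=Q, R=R, SQS=SQS,
                            spec=spec)
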