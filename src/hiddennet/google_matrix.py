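"""Google matrix construction and PageRank.

The Google matrix of a directed graph with N nodes is the column-stochastic
matrix ``G = alpha * S + (1 - alpha) / N`` where ``S[i, j] = A[i, j] / k_out(j)``
for nodes with outgoing links and ``S[:, j] = 1/N`` for dangling nodes
(no outgoing links).  The damping factor ``alpha`` (default 0.85) is the
probability of following a link rather than teleporting uniformly.

The two dense rank-one parts (dangling columns and teleportation) are never
materialized: matrix-vector products apply them analytically, so memory stays
proportional to the number of links.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph_core import DirectedGraph


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float | None = None, iterations: int | None = None):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class GoogleMatrix:
    """Column-stochastic Google matrix stored as sparse-plus-rank-one."""

    def __init__(self, graph: DirectedGraph, alpha: float = 0.85):
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
        self.alpha = float(alpha)
        self.n = graph.n_nodes
        k_out = graph.out_degrees()
        self.dangling = k_out == 0
        inv = np.zeros(self.n)
        inv[~self.dangling] = 1.0 / k_out[~self.dangling]
        # S0[i, j] = A[i, j] / k_out(j), zero columns for dangling nodes
        self.S0 = sp.csr_matrix(
            (inv[graph.edges[:, 0]], (graph.edges[:, 1], graph.edges[:, 0])),
            shape=(self.n, self.n),
        )

    def matvec(self, x: np.ndarray) -> np.ndarray:
        """Compute ``G @ x`` without densifying the rank-one parts."""
        x = np.asarray(x, dtype=float)
        uniform = (self.alpha * x[self.dangling].sum() + (1 - self.alpha) * x.sum()) / self.n
        return self.alpha * (self.S0 @ x) + uniform

    def rmatvec(self, x: np.ndarray) -> np.ndarray:
        """Compute ``G.T @ x``."""
        x = np.asarray(x, dtype=float)
        y = self.alpha * (self.S0.T @ x)
        y += (1 - self.alpha) / self.n * x.sum()
        y[self.dangling] += self.alpha / self.n * x.sum()
        return y

    def dense(self) -> np.ndarray:
        """Explicit dense G; intended for small N (oracles, reductions)."""
        S = self.S0.toarray()
        S[:, self.dangling] = 1.0 / self.n
        return self.alpha * S + (1 - self.alpha) / self.n


@dataclass(frozen=True)
class PageRankVector:
    """PageRank probabilities P and rank index K (1 = largest P)."""

    p: np.ndarray
    rank: np.ndarray  # K, a permutation of 1..N
    iterations: int
    residual: float

    def rank_of(self, node_ids: np.ndarray) -> np.ndarray:
        return self.rank[np.asarray(node_ids)]


def rank_index(p: np.ndarray) -> np.ndarray:
    """Descending-probability rank, 1-based; ties broken by ascending node id."""
    order = np.lexsort((np.arange(len(p)), -p))
    rank = np.empty(len(p), dtype=np.int64)
    rank[order] = np.arange(1, len(p) + 1)
    return rank


def pagerank(
    G: GoogleMatrix,
    tol: float = 1e-12,
    max_iter: int = 1000,
    x0: np.ndarray | None = None,
) -> PageRankVector:
    """Power iteration from the uniform vector until the L1 change < tol.

    The teleportation term guarantees a unique positive stationary vector, so
    the iteration is deterministic and always converges for alpha < 1; a
    failure to converge within ``max_iter`` raises :class:`ConvergenceError`
    carrying the last residual.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    x = np.full(G.n, 1.0 / G.n) if x0 is None else np.asarray(x0, dtype=float) / np.sum(x0)
    for it in range(1, max_iter + 1):
        y = G.matvec(x)
        y /= y.sum()  # guard drift; G is stochastic so this is ~1 already
        residual = float(np.abs(y - x).sum())
        x = y
        if residual < tol:
            return PageRankVector(p=x, rank=rank_index(x), iterations=it, residual=residual)
    raise ConvergenceError(
        f"PageRank did not converge in {max_iter} iterations (residual {residual:.3e})",
        residual=residual,
        iterations=max_iter,
    )


def pagerank_dense(M: np.ndarray, tol: float = 1e-14, max_iter: int = 100000) -> np.ndarray:
    """PageRank of an explicit column-stochastic matrix (reduced matrices)."""
    n = M.shape[0]
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        y = M @ x
        y /= y.sum()
        if np.abs(y - x).sum() < tol:
            return y
        x = y
    raise ConvergenceError("dense power iteration did not converge")
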