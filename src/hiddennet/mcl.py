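"""Markov Clustering (MCL) of the hidden-link network.

MCL alternates expansion (matrix power, spreading flow along paths) and
inflation (elementwise power + column renormalization, sharpening strong
flows) on a column-stochastic matrix until the flow settles on attractors;
the attractor structure then defines the clusters.  Defaults follow common
practice for weighted networks: inflation 2.0, expansion 2, symmetrization by
the maximum of the two arc directions, per-node self-loops at the maximum
incident weight, and discarding of clusters below a minimum size (default 4).

Everything is deterministic: identical inputs and parameters always yield the
identical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .google_matrix import ConvergenceError
from .hidden_network import ThresholdedNetwork


@dataclass
class Clustering:
    """Disjoint communities (global node ids), ordered by size descending."""

    communities: list[np.ndarray]
    params: dict
    n_iterations: int
    n_discarded: int = 0           # communities dropped for being below min_size
    discarded_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.communities)

    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.communities], dtype=np.int64)

    def labels(self) -> dict[int, int]:
        """node id -> community index for every clustered node."""
        return {int(v): k for k, comm in enumerate(self.communities) for v in comm}

    def as_sets(self) -> list[set[int]]:
        return [set(map(int, c)) for c in self.communities]


def _mcl_matrix(edges: np.ndarray, weights: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Symmetrized, self-looped, column-normalized dense flow matrix."""
    n = len(nodes)
    local = {int(v): k for k, v in enumerate(nodes)}
    W = np.zeros((n, n))
    for (a, b), w in zip(edges.tolist(), weights):
        i, j = local[a], local[b]
        W[i, j] = max(W[i, j], w)
    W = np.maximum(W, W.T)
    loops = W.max(axis=0)
    np.fill_diagonal(W, loops)
    return W / W.sum(axis=0)


def mcl_cluster(
    net: ThresholdedNetwork,
    inflation: float = 2.0,
    expansion: int = 2,
    min_size: int = 4,
    prune_threshold: float = 1e-5,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> Clustering:
    """Cluster the thresholded network's nodes by Markov Clustering.

    Nodes not incident to any kept arc are not clustered.  Clusters below
    ``min_size`` are discarded (their count and members are recorded on the
    result).  Raises :class:`ConvergenceError` if the flow matrix has not
    settled after ``max_iter`` rounds.
    """
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    if expansion < 2:
        raise ValueError("expansion must be an integer >= 2")
    nodes = net.node_ids()
    if len(nodes) == 0:
        raise ValueError("network has no edges to cluster")
    M = _mcl_matrix(net.edges, net.weights, nodes)
    for it in range(1, max_iter + 1):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M[M < prune_threshold] = 0.0
        colsum = M.sum(axis=0)
        if (colsum == 0).any():
            # pruning emptied a column; restore the node as its own attractor
            dead = np.flatnonzero(colsum == 0)
            M[dead, dead] = 1.0
            colsum = M.sum(axis=0)
        M = M / colsum
        if np.abs(M - prev).max() < tol:
            break
    else:
        raise ConvergenceError(
            f"MCL did not converge in {max_iter} iterations "
            f"(last change {np.abs(M - prev).max():.3e})"
        )
    communities = _clusters_from_attractors(M, nodes)
    communities.sort(key=lambda c: (-len(c), int(c.min())))
    kept = [c for c in communities if len(c) >= min_size]
    dropped = [c for c in communities if len(c) < min_size]
    return Clustering(
        communities=kept,
        params={
            "inflation": inflation,
            "expansion": expansion,
            "prune_threshold": prune_threshold,
            "min_size": min_size,
        },
        n_iterations=it,
        n_discarded=len(dropped),
        discarded_nodes=np.concatenate(dropped) if dropped else np.empty(0, dtype=np.int64),
    )


def _clusters_from_attractors(M: np.ndarray, nodes: np.ndarray) -> list[np.ndarray]:
    """Clusters from the converged flow matrix.

    Attractors are nodes with residual flow onto themselves.  Attractors are
    grouped into attractor systems (weak components of the nonzero structure
    restricted to attractor rows/columns); each remaining node joins the
    system of the attractor receiving most of its flow, ties to the smallest
    attractor index.
    """
    n = M.shape[0]
    attractors = np.flatnonzero(M.diagonal() > 0)
    if len(attractors) == 0:  # pathological; treat every node as its own attractor
        attractors = np.arange(n)
    sub = M[np.ix_(attractors, attractors)]
    _, sys_label = connected_components(sp.csr_matrix(sub != 0), directed=True, connection="weak")
    attr_system = dict(zip(attractors.tolist(), sys_label.tolist()))
    groups: dict[int, list[int]] = {}
    for j in range(n):
        flows = M[attractors, j]
        if flows.max() > 0:
            a = attractors[int(np.argmax(flows))]  # argmax ties -> smallest index
            lab = attr_system[int(a)]
        elif j in attr_system:
            lab = attr_system[j]
        else:  # no flow to any attractor: isolate
            lab = -1 - j
        groups.setdefault(lab, []).append(j)
    return [nodes[np.array(sorted(members))] for members in groups.values()]


def write_clustering(clustering: Clustering, path, params_path=None) -> None:
    import json

    import pandas as pd

    rows = [
        (cid, int(node))
        for cid, comm in enumerate(clustering.communities)
        for node in comm
    ]
    pd.DataFrame(rows, columns=["community_id", "node_id"]).to_csv(
        path, sep="\t", index=False
    )
    if params_path is not None:
        with open(params_path, "w") as fh:
            json.dump(
                {**clustering.params, "n_iterations": clustering.n_iterations,
                 "n_discarded": clustering.n_discarded},
                fh, indent=2,
            )
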