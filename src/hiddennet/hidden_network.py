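"""Hidden-link network: connectivity-matched thresholding of G_qr.

A hidden link is an above-cutoff off-diagonal entry of G_qr.  The cutoff is
not free: it is calibrated so that the largest connected component of the
hidden network has the same "connectivity" (nodes divided by edges) as the
LCC of the direct-link network on the same subset.  Because edge counts are
discrete, the matched ratio is the closest achievable one; ties go to the
larger cutoff (the sparser network).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_core import DirectedGraph, bidirectional_fraction, weakly_connected_lcc

WEIGHT_CLAMP = 1e-12  # round-off guard: weights below this are treated as zero


@dataclass
class ThresholdedNetwork:
    """Weighted arcs above a cutoff, with LCC connectivity metadata."""

    subset: np.ndarray           # global node ids the weight matrix is defined over
    edges: np.ndarray            # (m, 2) global-id arcs with weight > cutoff
    weights: np.ndarray
    cutoff: float
    lcc_ratio: float
    provenance: str = "hidden"   # "direct" | "hidden"
    lcc_nodes: int = 0
    lcc_edges: int = 0
    n_clamped: int = field(default=0, repr=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_ids(self) -> np.ndarray:
        """Distinct nodes incident to at least one kept arc."""
        return np.unique(self.edges) if self.edges.size else np.empty(0, dtype=np.int64)

    def arc_set(self) -> set[tuple[int, int]]:
        return set(map(tuple, self.edges.tolist()))

    def bidirectional_fraction(self) -> float:
        return bidirectional_fraction(self.edges)


class _UnionFind:
    """Union-find over local indices tracking component sizes and edge counts."""

    def __init__(self, n: int):
        self.parent = np.arange(n)
        self.size = np.ones(n, dtype=np.int64)
        self.n_edges = np.zeros(n, dtype=np.int64)
        self.min_id = np.arange(n)

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def add_edge(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            self.n_edges[ra] += 1
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        self.n_edges[ra] += self.n_edges[rb] + 1
        self.min_id[ra] = min(self.min_id[ra], self.min_id[rb])

    def lcc(self) -> tuple[int, int]:
        """(nodes, edges) of the largest component; ties -> smallest member id."""
        roots = np.unique([self.find(i) for i in range(len(self.parent))])
        sizes = self.size[roots]
        best = roots[sizes == sizes.max()]
        if len(best) > 1:
            best = [best[np.argmin(self.min_id[best])]]
        r = best[0]
        return int(self.size[r]), int(self.n_edges[r])


def _positive_offdiag(G_qr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    W = np.array(G_qr, dtype=float)
    np.fill_diagonal(W, 0.0)
    n_clamped = int(((W != 0) & (np.abs(W) < WEIGHT_CLAMP)).sum())
    W[np.abs(W) < WEIGHT_CLAMP] = 0.0
    rows, cols = np.nonzero(W > 0)
    return rows, cols, W[rows, cols], n_clamped


def lcc_ratio_of_arcs(edges: np.ndarray, n_nodes: int) -> float:
    """n/m of the largest weakly connected component of an arc set."""
    g = DirectedGraph.from_edges(n_nodes, edges, log_drops=False)
    _, m, ratio = weakly_connected_lcc(g)
    return ratio


def direct_network(direct_arcs: np.ndarray, subset: np.ndarray) -> ThresholdedNetwork:
    """Wrap the direct-link arcs on the subset as a ThresholdedNetwork."""
    subset = np.asarray(subset, dtype=np.int64)
    arcs = np.asarray(direct_arcs, dtype=np.int64).reshape(-1, 2)
    local = {int(v): k for k, v in enumerate(subset)}
    loc = np.array([[local[a], local[b]] for a, b in arcs.tolist()], dtype=np.int64)
    g = DirectedGraph.from_edges(len(subset), loc, log_drops=False)
    members, m, ratio = weakly_connected_lcc(g)
    return ThresholdedNetwork(
        subset=subset,
        edges=arcs,
        weights=np.ones(len(arcs)),
        cutoff=0.0,
        lcc_ratio=ratio,
        provenance="direct",
        lcc_nodes=len(members),
        lcc_edges=m,
    )


def select_cutoff(
    G_qr: np.ndarray,
    subset: np.ndarray,
    direct_arcs: np.ndarray,
    keep_diagonal: bool = False,
) -> ThresholdedNetwork:
    """Sweep candidate cutoffs on G_qr and match the direct LCC connectivity.

    Candidates are the distinct positive off-diagonal weights, swept in
    descending order with an incremental union-find, so the sweep is linear
    in the number of weighted arcs.  Returns the hidden network whose LCC
    nodes/edges ratio is closest to the direct network's; ties prefer the
    larger cutoff (fewer edges).
    """
    subset = np.asarray(subset, dtype=np.int64)
    n_r = len(subset)
    if G_qr.shape != (n_r, n_r):
        raise ValueError("G_qr shape does not match subset length")
    direct = direct_network(direct_arcs, subset)
    if keep_diagonal:
        G_qr = G_qr.copy()
    rows, cols, w, n_clamped = _positive_offdiag(G_qr)
    if keep_diagonal:
        d = np.diag(G_qr)
        keep = d > WEIGHT_CLAMP
        # self-loops never affect weak connectivity; appended after selection
    if len(w) == 0:
        raise ValueError("G_qr has no positive off-diagonal entries above the clamp")

    order = np.argsort(-w, kind="stable")
    rows, cols, w = rows[order], cols[order], w[order]
    distinct = np.unique(w)[::-1]  # descending distinct weights

    uf = _UnionFind(n_r)
    best = None  # (distance, class_index, lcc_n, lcc_m)
    pos = 0
    for k, wk in enumerate(distinct):
        while pos < len(w) and w[pos] >= wk:
            uf.add_edge(int(rows[pos]), int(cols[pos]))
            pos += 1
        n, m = uf.lcc()
        if m == 0:
            continue
        dist = abs(n / m - direct.lcc_ratio)
        if best is None or dist < best[0] - 1e-15:
            best = (dist, k, n, m)
    if best is None:
        raise ValueError("no candidate cutoff yields a component with edges")
    _, k_best, lcc_n, lcc_m = best
    cutoff = float(distinct[k_best + 1]) if k_best + 1 < len(distinct) else 0.0
    keep_mask = w >= distinct[k_best]
    # W[i, j] is the j -> i transition weight: arcs run column -> row
    edges = np.column_stack([subset[cols[keep_mask]], subset[rows[keep_mask]]])
    weights = w[keep_mask]
    if keep_diagonal:
        diag_nodes = subset[np.flatnonzero(keep & (d > cutoff))]
        if diag_nodes.size:
            edges = np.vstack([edges, np.column_stack([diag_nodes, diag_nodes])])
            weights = np.concatenate([weights, d[keep & (d > cutoff)]])
    return ThresholdedNetwork(
        subset=subset,
        edges=edges,
        weights=weights,
        cutoff=cutoff,
        lcc_ratio=lcc_n / lcc_m,
        provenance="hidden",
        lcc_nodes=lcc_n,
        lcc_edges=lcc_m,
        n_clamped=n_clamped,
    )


def threshold_at(G_qr: np.ndarray, subset: np.ndarray, cutoff: float) -> ThresholdedNetwork:
    """Hidden network at an explicit cutoff (weights strictly above it)."""
    subset = np.asarray(subset, dtype=np.int64)
    rows, cols, w, n_clamped = _positive_offdiag(G_qr)
    keep = w > cutoff
    edges = np.column_stack([subset[cols[keep]], subset[rows[keep]]])
    local = np.column_stack([cols[keep], rows[keep]])
    if len(edges):
        ratio = lcc_ratio_of_arcs(local, len(subset))
    else:
        ratio = float("nan")
    return ThresholdedNetwork(
        subset=subset, edges=edges, weights=w[keep], cutoff=float(cutoff),
        lcc_ratio=ratio, provenance="hidden", n_clamped=n_clamped,
    )


def link_overlap_stats(
    direct: ThresholdedNetwork | np.ndarray,
    hidden: ThresholdedNetwork,
) -> dict:
    """Arc-level overlap between direct and hidden networks on one subset."""
    if isinstance(direct, ThresholdedNetwork):
        if set(direct.subset.tolist()) != set(hidden.subset.tolist()):
            raise ValueError("direct and hidden networks are on different subsets")
        d = direct.arc_set()
    else:
        d = set(map(tuple, np.asarray(direct, dtype=np.int64).reshape(-1, 2).tolist()))
    h = hidden.arc_set()
    both = d & h
    stats = {
        "direct_only": len(d - h),
        "hidden_only": len(h - d),
        "direct_and_hidden": len(both),
        "fraction_direct_also_hidden": len(both) / len(d) if d else float("nan"),
        "fraction_hidden_also_direct": len(both) / len(h) if h else float("nan"),
    }
    return stats
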