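"""Friendship (augmented) networks, community labeling and path sampling.

For a community of marked nodes connected by hidden links, the friendship
network collects every page of the global graph mediating an oriented
length-2 path a -> v -> b between two hidden-link endpoints, together with
those arcs and any direct intra-community arcs.  Mediators outside the
community are the "associated" pages; the one with the largest total degree
in the augmented network names the community.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass

import numpy as np

from .graph_core import DirectedGraph, NodeTable

INF = float("inf")


@dataclass
class FriendshipNetwork:
    protein_nodes: np.ndarray       # community member ids
    associated_nodes: np.ndarray    # mediating page ids outside the community
    edges: np.ndarray               # (m, 2) arcs from the global graph
    degree: dict[int, int]          # total degree within this network
    mediators: dict[tuple[int, int], list[int]]  # hidden arc -> mediating pages


@dataclass
class CommunityLabel:
    label: str
    candidates: list[tuple[str, int]]  # (title, degree), ranked
    self_labeled: bool = False         # True when no associated node exists


def _adjacency_sets(graph: DirectedGraph) -> tuple[dict[int, set[int]], dict[int, set[int]]]:
    out_adj: dict[int, set[int]] = {}
    in_adj: dict[int, set[int]] = {}
    for a, b in graph.edges.tolist():
        out_adj.setdefault(a, set()).add(b)
        in_adj.setdefault(b, set()).add(a)
    return out_adj, in_adj


def build_friendship_network(
    global_graph: DirectedGraph,
    community: np.ndarray,
    hidden_links: np.ndarray,
) -> FriendshipNetwork:
    """Augment a community with all pages on oriented length-2 paths.

    For every hidden arc (a, b) within the community, every v with arcs
    a -> v and v -> b in the global graph is collected, the two arcs are
    included, and a direct arc a -> b is included when present.
    """
    community = np.asarray(community, dtype=np.int64)
    if community.size == 0:
        raise ValueError("community is empty")
    comm_set = set(community.tolist())
    hidden_links = np.asarray(hidden_links, dtype=np.int64).reshape(-1, 2)
    for a, b in hidden_links.tolist():
        if a not in comm_set or b not in comm_set:
            raise ValueError(f"hidden link ({a}, {b}) leaves the community")
    out_adj, in_adj = _adjacency_sets(global_graph)
    edge_set = global_graph.edge_set()
    edges: set[tuple[int, int]] = set()
    mediators: dict[tuple[int, int], list[int]] = {}
    associated: set[int] = set()
    for a, b in hidden_links.tolist():
        vs = sorted(out_adj.get(a, set()) & in_adj.get(b, set()))
        mediators[(a, b)] = vs
        for v in vs:
            edges.add((a, v))
            edges.add((v, b))
            if v not in comm_set:
                associated.add(v)
        if (a, b) in edge_set:
            edges.add((a, b))
    degree: Counter[int] = Counter()
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1
    edge_arr = (
        np.array(sorted(edges), dtype=np.int64) if edges else np.empty((0, 2), dtype=np.int64)
    )
    return FriendshipNetwork(
        protein_nodes=community,
        associated_nodes=np.array(sorted(associated), dtype=np.int64),
        edges=edge_arr,
        degree=dict(degree),
        mediators=mediators,
    )


def label_community(fn: FriendshipNetwork, nodes: NodeTable, top_k: int = 10) -> CommunityLabel:
    """Name the community after its most connected associated page.

    Candidates are ranked by degree descending, ties broken lexicographically
    by title; the top ``top_k`` are returned so a curator can override the
    automatic choice.  With no associated pages the community is labeled by
    its own max-degree member and flagged ``self_labeled``.
    """
    pool = fn.associated_nodes
    self_labeled = False
    if pool.size == 0:
        pool = fn.protein_nodes
        self_labeled = True
    ranked = sorted(
        ((nodes.title(int(v)), fn.degree.get(int(v), 0)) for v in pool),
        key=lambda t: (-t[1], t[0]),
    )
    return CommunityLabel(
        label=ranked[0][0], candidates=ranked[:top_k], self_labeled=self_labeled
    )


def bfs_shortest_path_length(
    out_adj: dict[int, set[int]], source: int, target: int
) -> float:
    """Length of the shortest oriented path source -> target (inf if none)."""
    if source == target:
        return 0
    seen = {source}
    frontier = deque([(source, 0)])
    while frontier:
        v, d = frontier.popleft()
        for w in out_adj.get(v, ()):  # noqa: B905 - set iteration
            if w == target:
                return d + 1
            if w not in seen:
                seen.add(w)
                frontier.append((w, d + 1))
    return INF


@dataclass
class PathLengthHistogram:
    counts: dict            # length (int) or inf -> count
    n_pairs: int

    def modal_length(self) -> int:
        """Most frequent finite length; ties broken toward the shorter one."""
        finite = {k: v for k, v in self.counts.items() if k != INF}
        if not finite:
            raise ValueError("no finite path lengths observed")
        return min(sorted(finite), key=lambda k: (-finite[k], k))


def sampled_shortest_paths(
    global_graph: DirectedGraph,
    pairs: np.ndarray | None = None,
    *,
    n_pairs: int = 1000,
    seed: int = 42,
    pair_kind: str = "explicit",
    protein_ids: np.ndarray | None = None,
    hidden_arcs: np.ndarray | None = None,
) -> PathLengthHistogram:
    """Histogram of shortest oriented path lengths over sampled node pairs.

    ``pair_kind`` selects the sampler: ``explicit`` (pairs given),
    ``random_any`` (uniform distinct pairs), ``random_protein`` (uniform
    distinct marked pairs; requires ``protein_ids``), or
    ``hidden_link_endpoints`` (uniform over ``hidden_arcs``).  Unreachable
    pairs land in a separate infinity bin; counts always sum to the number of
    sampled pairs.
    """
    rng = np.random.default_rng(seed)
    if pair_kind == "explicit":
        if pairs is None:
            raise ValueError("explicit pair_kind requires pairs")
        sampled = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    else:
        if n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        if pair_kind == "random_any":
            pool = np.arange(global_graph.n_nodes)
        elif pair_kind == "random_protein":
            if protein_ids is None:
                raise ValueError("random_protein requires protein_ids")
            pool = np.asarray(protein_ids, dtype=np.int64)
        elif pair_kind == "hidden_link_endpoints":
            if hidden_arcs is None or len(hidden_arcs) == 0:
                raise ValueError("hidden_link_endpoints requires non-empty hidden_arcs")
            arcs = np.asarray(hidden_arcs, dtype=np.int64).reshape(-1, 2)
            idx = rng.integers(0, len(arcs), size=n_pairs)
            sampled = arcs[idx]
            pool = None
        else:
            raise ValueError(f"unknown pair_kind {pair_kind!r}")
        if pair_kind != "hidden_link_endpoints":
            src = rng.choice(pool, size=n_pairs)
            dst = rng.choice(pool, size=n_pairs)
            clash = src == dst
            while clash.any():
                dst[clash] = rng.choice(pool, size=int(clash.sum()))
                clash = src == dst
            sampled = np.column_stack([src, dst])
    out_adj, _ = _adjacency_sets(global_graph)
    counts: Counter = Counter()
    for s, t in sampled.tolist():
        d = bfs_shortest_path_length(out_adj, s, t)
        counts[d if d == INF else int(d)] += 1
    return PathLengthHistogram(counts=dict(counts), n_pairs=len(sampled))


def community_graph(clustering, hidden_net) -> "np.ndarray":
    """Abstracted community-of-communities graph.

    Counts hidden arcs of the thresholded network running between members of
    each ordered community pair (and within one community on the diagonal
    pair (c, c)).  Returns a record array of (comm_a, comm_b, n_hidden_links).
    """
    import pandas as pd

    labels = clustering.labels()
    counter: Counter = Counter()
    for a, b in hidden_net.edges.tolist():
        ca, cb = labels.get(a), labels.get(b)
        if ca is None or cb is None:
            continue
        counter[(ca, cb)] += 1
    rows = [(a, b, n) for (a, b), n in sorted(counter.items())]
    return pd.DataFrame(rows, columns=["comm_a", "comm_b", "n_hidden_links"])
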