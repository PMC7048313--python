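"""Directed-graph data model, edge-list I/O and elementary statistics.

The global graph is a plain directed graph over dense 0-based integer node
ids.  Node metadata (page title, marked "protein" flag, optional gene symbol)
lives in a separate :class:`NodeTable`; matrices and edge arrays only ever see
integer ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

NODE_TABLE_COLUMNS = ["node_id", "title", "is_protein", "symbol"]


class GraphFormatError(ValueError):
    """Raised for malformed edge-list or node-table input."""


@dataclass(frozen=True)
class NodeTable:
    """Node metadata: title, marked-subset flag and optional gene symbol.

    Invariants: node ids are exactly ``0..N-1``, titles are unique, and a
    symbol (when present) belongs to exactly one node.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in NODE_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise GraphFormatError(f"node table missing columns: {missing}")
        n = len(df)
        ids = df["node_id"].to_numpy()
        if not np.array_equal(np.sort(ids), np.arange(n)):
            raise GraphFormatError("node_id must be a dense 0..N-1 index")
        if df["title"].duplicated().any():
            dup = df.loc[df["title"].duplicated(), "title"].iloc[0]
            raise GraphFormatError(f"duplicate title: {dup!r}")
        syms = df["symbol"].dropna()
        syms = syms[syms != ""]
        if syms.duplicated().any():
            raise GraphFormatError("a gene symbol is attached to more than one node")
        object.__setattr__(self, "frame", df.set_index("node_id", drop=False).sort_index())

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def protein_ids(self) -> np.ndarray:
        """Ids of the marked (protein) nodes, ascending."""
        return self.frame.index[self.frame["is_protein"].astype(bool)].to_numpy()

    def title(self, node_id: int) -> str:
        return self.frame.at[node_id, "title"]

    def symbol_map(self) -> dict[int, str]:
        """node_id -> symbol for nodes that carry a non-empty symbol."""
        s = self.frame["symbol"].dropna()
        s = s[s != ""]
        return s.to_dict()


@dataclass
class DirectedGraph:
    """A deduplicated directed graph without self-loops.

    ``edges`` is an ``(m, 2)`` integer array of ``(source, target)`` arcs in
    lexicographic order; ``weights`` is optional and aligned with ``edges``.
    """

    n_nodes: int
    edges: np.ndarray
    weights: np.ndarray | None = None
    _edge_set: set[tuple[int, int]] | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_edges(
        cls,
        n_nodes: int,
        edges: np.ndarray,
        weights: np.ndarray | None = None,
        log_drops: bool = True,
    ) -> "DirectedGraph":
        """Build a graph, collapsing duplicate arcs and dropping self-loops."""
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges.size and (edges.min() < 0 or edges.max() >= n_nodes):
            bad = edges[(edges < 0).any(axis=1) | (edges >= n_nodes).any(axis=1)][0]
            raise GraphFormatError(
                f"edge {tuple(bad)} references a node outside 0..{n_nodes - 1}"
            )
        loops = edges[:, 0] == edges[:, 1]
        n_loops = int(loops.sum())
        if n_loops and log_drops:
            logger.info("dropped %d self-loop(s)", n_loops)
        edges = edges[~loops]
        if weights is not None:
            weights = np.asarray(weights, dtype=float)[~loops]
            uniq, idx = np.unique(edges, axis=0, return_index=True)
            weights = weights[idx]
            edges = uniq
        else:
            edges = np.unique(edges, axis=0) if edges.size else edges.reshape(0, 2)
        return cls(n_nodes=n_nodes, edges=edges, weights=weights)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[int, int]]:
        if self._edge_set is None:
            self._edge_set = set(map(tuple, self.edges.tolist()))
        return self._edge_set

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.edges[:, 0], minlength=self.n_nodes)

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.edges[:, 1], minlength=self.n_nodes)

    def adjacency(self) -> sp.csr_matrix:
        """Sparse adjacency with ``A[i, j] = 1`` when node j points to node i."""
        m = self.n_edges
        data = np.ones(m) if self.weights is None else self.weights
        return sp.csr_matrix(
            (data, (self.edges[:, 1], self.edges[:, 0])),
            shape=(self.n_nodes, self.n_nodes),
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges.tolist()))
        return g

    def induced_arcs(self, subset: np.ndarray) -> np.ndarray:
        """Arcs with both endpoints in ``subset`` (global ids preserved)."""
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[np.asarray(subset)] = True
        keep = mask[self.edges[:, 0]] & mask[self.edges[:, 1]]
        return self.edges[keep]


def read_edgelist(path, node_table_path=None) -> tuple[DirectedGraph, NodeTable | None]:
    """Read a two-column TSV edge list (``#`` comments) plus optional node table.

    Duplicate rows collapse to one arc, self-loops are dropped (logged), and
    any endpoint outside the node table's range raises
    :class:`GraphFormatError` naming the offending value.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=["source", "target"],
            dtype=str, skip_blank_lines=True,
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas-level failure
        raise GraphFormatError(f"cannot parse edge list {path}: {exc}") from exc
    for col in ("source", "target"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted != converted.round())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise GraphFormatError(
                f"{path}: malformed row {row + 1}: {df.iloc[row].tolist()!r}"
            )
        df[col] = converted.astype(np.int64)
    edges = df.to_numpy(dtype=np.int64)

    nodes = read_node_table(node_table_path) if node_table_path is not None else None
    if nodes is not None:
        n = len(nodes)
    else:
        n = int(edges.max()) + 1 if edges.size else 0
    graph = DirectedGraph.from_edges(n, edges)
    return graph, nodes


def read_node_table(path) -> NodeTable:
    df = pd.read_csv(path, sep="\t", dtype={"title": str, "symbol": str})
    if "is_protein" in df.columns:
        df["is_protein"] = df["is_protein"].astype(int).astype(bool)
    if "symbol" not in df.columns:
        df["symbol"] = pd.NA
    return NodeTable(df[NODE_TABLE_COLUMNS].copy())


def write_edgelist(graph: DirectedGraph, path) -> None:
    pd.DataFrame(graph.edges, columns=["source", "target"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_node_table(nodes: NodeTable, path) -> None:
    out = nodes.frame[NODE_TABLE_COLUMNS].copy()
    out["is_protein"] = out["is_protein"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def weakly_connected_lcc(graph: DirectedGraph) -> tuple[np.ndarray, int, float]:
    """Largest weakly connected component: (node ids, edge count, n/m ratio).

    The "connectivity" ratio is the component's node count divided by the
    number of arcs with both endpoints inside it.  Ties for largest are broken
    by the smallest contained node id.  A graph with zero edges has no defined
    ratio and raises ``ValueError``.
    """
    if graph.n_edges == 0:
        raise ValueError("connectivity ratio undefined for a graph with zero edges")
    adj = sp.csr_matrix(
        (np.ones(graph.n_edges), (graph.edges[:, 0], graph.edges[:, 1])),
        shape=(graph.n_nodes, graph.n_nodes),
    )
    _, labels = connected_components(adj, directed=True, connection="weak")
    sizes = np.bincount(labels)
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:
        # tie -> component containing the smallest node id
        first_member = np.array([np.flatnonzero(labels == c)[0] for c in best])
        best = [best[np.argmin(first_member)]]
    comp = int(best[0])
    members = np.flatnonzero(labels == comp)
    inside = (labels[graph.edges[:, 0]] == comp) & (labels[graph.edges[:, 1]] == comp)
    m = int(inside.sum())
    if m == 0:
        raise ValueError("largest component contains no edges")
    return members, m, len(members) / m


def component_sizes(graph: DirectedGraph) -> np.ndarray:
    """Sizes of all weakly connected components (including isolated nodes)."""
    adj = sp.csr_matrix(
        (np.ones(graph.n_edges), (graph.edges[:, 0], graph.edges[:, 1])),
        shape=(graph.n_nodes, graph.n_nodes),
    )
    _, labels = connected_components(adj, directed=True, connection="weak")
    return np.bincount(labels)


def bidirectional_fraction(arcs) -> float:
    """Fraction of arcs whose reciprocal arc is also present."""
    if isinstance(arcs, DirectedGraph):
        arc_set = arcs.edge_set()
    else:
        arc_set = set(map(tuple, np.asarray(arcs, dtype=np.int64).reshape(-1, 2).tolist()))
    if not arc_set:
        raise ValueError("bidirectional fraction undefined for zero edges")
    recip = sum(1 for (a, b) in arc_set if (b, a) in arc_set)
    return recip / len(arc_set)


def flag_isolated_marked_nodes(graph: DirectedGraph, nodes: NodeTable) -> pd.DataFrame:
    """Flag marked nodes with no links at all / none to other marked nodes.

    Returns a frame indexed by protein node id with two boolean columns:
    ``isolated_global`` (no in- or out-links to any page) and
    ``isolated_marked`` (none to other marked pages).  The pipeline filters on
    ``isolated_global`` by default; both views are exposed because either
    reading of "not having any outgoing or incoming links" is defensible.
    """
    prot = nodes.protein_ids
    deg_all = graph.out_degrees() + graph.in_degrees()
    marked_arcs = graph.induced_arcs(prot)
    deg_marked = np.zeros(graph.n_nodes, dtype=np.int64)
    if marked_arcs.size:
        deg_marked += np.bincount(marked_arcs[:, 0], minlength=graph.n_nodes)
        deg_marked += np.bincount(marked_arcs[:, 1], minlength=graph.n_nodes)
    return pd.DataFrame(
        {
            "isolated_global": deg_all[prot] == 0,
            "isolated_marked": deg_marked[prot] == 0,
        },
        index=pd.Index(prot, name="node_id"),
    )
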