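import numpy as np
import pandas as pd
import pytest

from hiddennet.graph_core import (
    DirectedGraph,
    GraphFormatError,
    NodeTable,
    bidirectional_fraction,
    component_sizes,
    flag_isolated_marked_nodes,
    read_edgelist,
    read_node_table,
    weakly_connected_lcc,
    write_edgelist,
    write_node_table,
)

from .conftest import random_graph


def make_nodes(n, protein_ids=(), symbols=None):
    rows = []
    for i in range(n):
        rows.append(
            {
                "node_id": i,
                "title": f"T{i}",
                "is_protein": i in protein_ids,
                "symbol": (symbols or {}).get(i, pd.NA),
            }
        )
    return NodeTable(pd.DataFrame(rows))


class TestLoading:
    def test_duplicate_rows_collapse(self):
        g = DirectedGraph.from_edges(3, [(0, 1), (0, 1), (1, 0)])
        assert g.n_edges == 2

    def test_self_loop_dropped(self, caplog):
        with caplog.at_level("INFO", logger="hiddennet.graph_core"):
            g = DirectedGraph.from_edges(3, [(2, 2), (0, 1)])
        assert g.n_edges == 1
        assert "self-loop" in caplog.text

    def test_out_of_range_node_rejected(self):
        with pytest.raises(GraphFormatError, match="99"):
            DirectedGraph.from_edges(10, [(0, 99)])

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("0\t1\n1\tfoo\n")
        with pytest.raises(GraphFormatError, match="row 2"):
            read_edgelist(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_edgelist(tmp_path / "absent.tsv")

    def test_roundtrip_identity(self, tmp_path):
        g = random_graph(3)
        nodes = make_nodes(g.n_nodes, protein_ids=(1, 2), symbols={1: "A", 2: "B"})
        write_edgelist(g, tmp_path / "e.tsv")
        write_node_table(nodes, tmp_path / "n.tsv")
        g2, n2 = read_edgelist(tmp_path / "e.tsv", tmp_path / "n.tsv")
        assert np.array_equal(g.edges, g2.edges)
        assert list(n2.protein_ids) == [1, 2]
        assert n2.symbol_map() == {1: "A", 2: "B"}


class TestNodeTable:
    def test_dense_ids_required(self):
        df = pd.DataFrame(
            {"node_id": [0, 2], "title": ["a", "b"], "is_protein": [0, 1],
             "symbol": [pd.NA, pd.NA]}
        )
        with pytest.raises(GraphFormatError, match="dense"):
            NodeTable(df)

    def test_duplicate_titles_rejected(self):
        df = pd.DataFrame(
            {"node_id": [0, 1], "title": ["a", "a"], "is_protein": [0, 0],
             "symbol": [pd.NA, pd.NA]}
        )
        with pytest.raises(GraphFormatError, match="duplicate title"):
            NodeTable(df)

    def test_duplicate_symbols_rejected(self):
        df = pd.DataFrame(
            {"node_id": [0, 1], "title": ["a", "b"], "is_protein": [1, 1],
             "symbol": ["X", "X"]}
        )
        with pytest.raises(GraphFormatError, match="symbol"):
            NodeTable(df)


class TestLcc:
    def test_two_cycles_tie_breaks_to_smallest_id(self):
        # two disjoint 3-cycles + isolated node 6: tie broken to {0,1,2}
        edges = [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)]
        g = DirectedGraph.from_edges(7, edges)
        members, m, ratio = weakly_connected_lcc(g)
        assert sorted(members) == [0, 1, 2]
        assert (m, ratio) == (3, 1.0)

    def test_path_graph(self):
        g = DirectedGraph.from_edges(4, [(0, 1), (1, 2), (2, 3)])
        members, m, ratio = weakly_connected_lcc(g)
        assert len(members) == 4 and m == 3 and ratio == pytest.approx(4 / 3)

    def test_bidirected_k4(self):
        edges = [(i, j) for i in range(4) for j in range(4) if i != j]
        g = DirectedGraph.from_edges(4, edges)
        members, m, ratio = weakly_connected_lcc(g)
        assert len(members) == 4 and m == 12 and ratio == pytest.approx(1 / 3)

    def test_zero_edges_is_error(self):
        with pytest.raises(ValueError, match="zero edges"):
            weakly_connected_lcc(DirectedGraph.from_edges(3, np.empty((0, 2))))

    def test_component_sizes_partition_nodes(self):
        g = random_graph(11)
        assert component_sizes(g).sum() == g.n_nodes


class TestBidirectionalFraction:
    @pytest.mark.parametrize(
        "edges,expected",
        [
            ([(0, 1), (1, 0)], 1.0),
            ([(0, 1), (1, 2)], 0.0),
            ([(0, 1), (1, 0), (1, 2), (2, 3)], 0.5),
        ],
    )
    def test_examples(self, edges, expected):
        assert bidirectional_fraction(np.array(edges)) == pytest.approx(expected)

    def test_zero_edges_is_error(self):
        with pytest.raises(ValueError):
            bidirectional_fraction(np.empty((0, 2)))

    def test_invariant_under_relabeling(self):
        g = random_graph(7)
        rng = np.random.default_rng(0)
        perm = rng.permutation(g.n_nodes)
        relabeled = perm[g.edges]
        assert bidirectional_fraction(g.edges) == pytest.approx(
            bidirectional_fraction(relabeled)
        )


def test_flag_isolated_marked_nodes():
    # protein 3 fully isolated; protein 4 linked only to background node 0
    g = DirectedGraph.from_edges(5, [(0, 1), (4, 0), (2, 4)])
    nodes = make_nodes(5, protein_ids=(2, 3, 4))
    flags = flag_isolated_marked_nodes(g, nodes)
    assert bool(flags.loc[3, "isolated_global"]) is True
    assert bool(flags.loc[4, "isolated_global"]) is False
    assert bool(flags.loc[4, "isolated_marked"]) is False  # 2 -> 4 is marked-marked
    assert bool(flags.loc[2, "isolated_marked"]) is False
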