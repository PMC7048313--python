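import numpy as np
import pandas as pd
import pytest

from hiddennet.friendship import (
    INF,
    PathLengthHistogram,
    bfs_shortest_path_length,
    build_friendship_network,
    community_graph,
    label_community,
    sampled_shortest_paths,
)
from hiddennet.graph_core import DirectedGraph, NodeTable


def make_nodes(titles, protein_ids=()):
    return NodeTable(
        pd.DataFrame(
            {
                "node_id": range(len(titles)),
                "title": titles,
                "is_protein": [i in protein_ids for i in range(len(titles))],
                "symbol": pd.NA,
            }
        )
    )


class TestFriendshipNetwork:
    def test_single_mediated_path(self):
        # A=0, T=1, B=2: hidden link A->B mediated by T
        g = DirectedGraph.from_edges(3, [(0, 1), (1, 2)])
        fn = build_friendship_network(g, np.array([0, 2]), np.array([(0, 2)]))
        assert list(fn.associated_nodes) == [1]
        assert fn.edges.tolist() == [[0, 1], [1, 2]]
        assert fn.degree == {0: 1, 1: 2, 2: 1}

    def test_no_mediator_yields_empty_associated(self):
        g = DirectedGraph.from_edges(3, [(0, 1)])
        fn = build_friendship_network(g, np.array([0, 2]), np.array([(0, 2)]))
        assert fn.associated_nodes.size == 0

    def test_direct_arc_included(self):
        g = DirectedGraph.from_edges(3, [(0, 1), (1, 2), (0, 2)])
        fn = build_friendship_network(g, np.array([0, 2]), np.array([(0, 2)]))
        assert [0, 2] in fn.edges.tolist()

    def test_mediating_community_member_not_associated(self):
        g = DirectedGraph.from_edges(3, [(0, 1), (1, 2)])
        fn = build_friendship_network(g, np.array([0, 1, 2]), np.array([(0, 2)]))
        assert fn.associated_nodes.size == 0
        assert fn.mediators[(0, 2)] == [1]

    def test_every_associated_node_certified_by_a_path(self, default_analysis):
        res = default_analysis
        es = res.graph.edge_set()
        comm = res.clustering.communities[0]
        cs = set(comm.tolist())
        links = np.array(
            [e for e in res.hidden.edges.tolist() if e[0] in cs and e[1] in cs]
        )
        fn = build_friendship_network(res.graph, comm, links)
        assert fn.associated_nodes.size
        for v in fn.associated_nodes:
            assert any(
                (a, int(v)) in es and (int(v), b) in es for a, b in links.tolist()
            )

    def test_empty_community_rejected(self):
        g = DirectedGraph.from_edges(2, [(0, 1)])
        with pytest.raises(ValueError, match="empty"):
            build_friendship_network(g, np.array([]), np.empty((0, 2)))


class TestLabeling:
    def test_max_degree_rule(self):
        g = DirectedGraph.from_edges(
            5, [(0, 2), (2, 1), (0, 3), (3, 1), (2, 3), (3, 2), (0, 4), (4, 1)]
        )
        nodes = make_nodes(["P0", "P1", "Apoptosis", "Zinc", "Iron"], protein_ids=(0, 1))
        fn = build_friendship_network(g, np.array([0, 1]), np.array([(0, 1)]))
        lab = label_community(fn, nodes)
        assert lab.label in {"Apoptosis", "Zinc", "Iron"}
        assert lab.candidates[0][1] >= lab.candidates[-1][1]
        assert not lab.self_labeled

    def test_lexicographic_tie_break(self):
        g = DirectedGraph.from_edges(4, [(0, 2), (2, 1), (0, 3), (3, 1)])
        nodes = make_nodes(["P0", "P1", "Zinc", "Apoptosis"], protein_ids=(0, 1))
        fn = build_friendship_network(g, np.array([0, 1]), np.array([(0, 1)]))
        assert label_community(fn, nodes).label == "Apoptosis"

    def test_self_label_fallback(self):
        g = DirectedGraph.from_edges(2, [(0, 1)])
        nodes = make_nodes(["P0", "P1"], protein_ids=(0, 1))
        fn = build_friendship_network(g, np.array([0, 1]), np.array([(0, 1)]))
        lab = label_community(fn, nodes)
        assert lab.self_labeled and lab.label in {"P0", "P1"}

    def test_planted_hub_title_wins(self, default_setup, default_analysis):
        _, graph, nodes, truth = default_setup
        res = default_analysis
        hub_titles = {f"Topic_{c}" for c in truth.hubs}
        hits = sum(lab.label in hub_titles for lab in res.labels)
        assert hits >= 0.8 * len(res.labels)


class TestShortestPaths:
    def test_direct_arc_length_one(self):
        g = DirectedGraph.from_edges(3, [(0, 1)])
        h = sampled_shortest_paths(g, pairs=np.array([(0, 1)]))
        assert h.counts == {1: 1}

    def test_mediated_length_two(self):
        g = DirectedGraph.from_edges(3, [(0, 1), (1, 2)])
        h = sampled_shortest_paths(g, pairs=np.array([(0, 2)]))
        assert h.counts == {2: 1}

    def test_unreachable_goes_to_inf_bin(self):
        g = DirectedGraph.from_edges(3, [(0, 1)])
        h = sampled_shortest_paths(g, pairs=np.array([(1, 0), (0, 1)]))
        assert h.counts[INF] == 1 and h.counts[1] == 1

    def test_counts_sum_to_pairs(self, default_setup):
        _, graph, nodes, _ = default_setup
        h = sampled_shortest_paths(
            graph, pair_kind="random_protein", protein_ids=nodes.protein_ids,
            n_pairs=200, seed=3,
        )
        assert sum(h.counts.values()) == 200 == h.n_pairs

    def test_modal_length_requires_finite(self):
        with pytest.raises(ValueError):
            PathLengthHistogram(counts={INF: 5}, n_pairs=5).modal_length()

    def test_invalid_n_pairs(self):
        g = DirectedGraph.from_edges(2, [(0, 1)])
        with pytest.raises(ValueError, match="n_pairs"):
            sampled_shortest_paths(g, pair_kind="random_any", n_pairs=0)

    def test_bfs_zero_for_same_node(self):
        assert bfs_shortest_path_length({0: {1}}, 0, 0) == 0


def test_community_graph_counts_intercommunity_arcs(default_analysis):
    df = community_graph(default_analysis.clustering, default_analysis.hidden)
    assert set(df.columns) == {"comm_a", "comm_b", "n_hidden_links"}
    intra = df[df.comm_a == df.comm_b].n_hidden_links.sum()
    inter = df[df.comm_a != df.comm_b].n_hidden_links.sum()
    assert intra > inter > 0  # communities are tight but weakly interlinked
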