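"""Shared fixtures: small deterministic graphs and the (expensive) default
synthetic pipeline products, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from hiddennet.evolution import link_persistence, match_communities
from hiddennet.graph_core import DirectedGraph
from hiddennet.pipeline import analyze, recovery_ari
from hiddennet.synthetic_data import SyntheticSpec, generate_global_graph, generate_snapshot_pair


def random_graph(seed: int, n: int | None = None) -> DirectedGraph:
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 200)) if n is None else n
    m = int(rng.integers(n, 6 * n))
    return DirectedGraph.from_edges(n, rng.integers(0, n, size=(m, 2)), log_drops=False)


@pytest.fixture(scope="session")
def default_setup():
    spec = SyntheticSpec()
    graph, nodes, truth = generate_global_graph(spec)
    return spec, graph, nodes, truth


@pytest.fixture(scope="session")
def default_analysis(default_setup):
    _, graph, nodes, _ = default_setup
    return analyze(graph, nodes)


@pytest.fixture(scope="session")
def default_ari(default_setup, default_analysis):
    _, _, _, truth = default_setup
    return recovery_ari(default_analysis, truth)


@pytest.fixture(scope="session")
def snapshot_runs():
    """Old/new pipeline products for 5 seeded snapshot pairs."""
    runs = []
    for seed in range(5):
        spec = SyntheticSpec(seed=seed)
        g_old, n_old, t_old, g_new, n_new, t_new = generate_snapshot_pair(
            spec, rewire_hub_frac=0.3, rewire_direct_frac=0.05, growth=1.2
        )
        res_old = analyze(g_old, n_old, with_labels=False)
        res_new = analyze(g_new, n_new, with_labels=False)
        shared = set(map(int, n_old.protein_ids))
        runs.append(
            {
                "seed": seed,
                "res_old": res_old,
                "res_new": res_new,
                "graph_new": g_new,
                "shared": shared,
                "direct_persistence": link_persistence(
                    res_old.direct.edges, g_new.induced_arcs(res_new.subset), shared
                ),
                "hidden_persistence": link_persistence(
                    res_old.hidden.edges, res_new.hidden.edges, shared
                ),
                "matches": match_communities(
                    res_old.clustering, res_new.clustering,
                    min_intersection=3, shared_nodes=shared,
                ),
            }
        )
    return runs
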