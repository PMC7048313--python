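"""End-to-end orchestration: PageRank -> REGOMAX -> cutoff -> MCL -> labels.

`analyze` is the library-level pipeline used by the tests, the acceptance
script and the CLI; `run_pipeline` is the file-level wrapper that reads a
config, writes every stage output and a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .friendship import build_friendship_network, label_community
from .google_matrix import GoogleMatrix, PageRankVector, pagerank
from .graph_core import (
    DirectedGraph,
    NodeTable,
    read_edgelist,
    write_edgelist,
    write_node_table,
)
from .hidden_network import ThresholdedNetwork, direct_network, select_cutoff
from .mcl import Clustering, mcl_cluster, write_clustering
from .regomax import ReducedGoogleMatrix, reduce_exact, reduce_projector_series, save_reduced

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Pipeline parameters; the defaults are the study's standard settings."""

    alpha: float = 0.85
    pr_tol: float = 1e-12
    pr_max_iter: int = 1000
    series_eps: float = 1e-12
    inflation: float = 2.0
    expansion: int = 2
    min_size: int = 4
    prune_threshold: float = 1e-5
    min_intersection: int = 3
    enrich_min_overlap: int = 5
    enrich_q_max: float = 1e-8
    keep_diagonal: bool = False
    label_top_k: int = 10
    seed: int = 42
    exact_below: int = 0   # use the dense-solve reduction when N <= this


@dataclass
class HiddenAnalysis:
    """All per-snapshot pipeline products."""

    graph: DirectedGraph
    nodes: NodeTable | None
    subset: np.ndarray
    pagerank: PageRankVector
    reduced: ReducedGoogleMatrix
    direct: ThresholdedNetwork
    hidden: ThresholdedNetwork
    clustering: Clustering
    labels: list = field(default_factory=list)

    def subset_ranks(self) -> dict[int, int]:
        """Global PageRank index K restricted to the subset."""
        return {int(v): int(self.pagerank.rank[v]) for v in self.subset}


def analyze(
    graph: DirectedGraph,
    nodes: NodeTable | None = None,
    subset: np.ndarray | None = None,
    config: PipelineConfig | None = None,
    with_labels: bool = True,
) -> HiddenAnalysis:
    """Run the full hidden-link analysis for one snapshot."""
    cfg = config or PipelineConfig()
    if subset is None:
        if nodes is None:
            raise ValueError("need either an explicit subset or a node table")
        subset = nodes.protein_ids
    subset = np.asarray(subset, dtype=np.int64)
    G = GoogleMatrix(graph, alpha=cfg.alpha)
    pr = pagerank(G, tol=cfg.pr_tol, max_iter=cfg.pr_max_iter)
    if graph.n_nodes <= cfg.exact_below:
        rgm = reduce_exact(G, subset)
    else:
        rgm = reduce_projector_series(G, subset, eps=cfg.series_eps)
    direct_arcs = graph.induced_arcs(subset)
    direct = direct_network(direct_arcs, subset)
    hidden = select_cutoff(rgm.G_qr, subset, direct_arcs, keep_diagonal=cfg.keep_diagonal)
    clustering = mcl_cluster(
        hidden,
        inflation=cfg.inflation,
        expansion=cfg.expansion,
        min_size=cfg.min_size,
        prune_threshold=cfg.prune_threshold,
    )
    labels = []
    if with_labels and nodes is not None:
        comm_arcs = {tuple(e) for e in hidden.edges.tolist()}
        for comm in clustering.communities:
            cs = set(comm.tolist())
            links = np.array(
                [e for e in comm_arcs if e[0] in cs and e[1] in cs], dtype=np.int64
            ).reshape(-1, 2)
            fn = build_friendship_network(graph, comm, links)
            labels.append(label_community(fn, nodes, top_k=cfg.label_top_k))
    return HiddenAnalysis(
        graph=graph, nodes=nodes, subset=subset, pagerank=pr, reduced=rgm,
        direct=direct, hidden=hidden, clustering=clustering, labels=labels,
    )


def run_pipeline(
    edges_path,
    nodes_path,
    out_dir,
    config: PipelineConfig | None = None,
) -> dict:
    """File-level pipeline: read inputs, run `analyze`, write all outputs.

    Returns the manifest dict (also written to ``manifest.json``).  Any stage
    failure propagates with the stage recorded in the manifest's log; outputs
    written before the failure are retained.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "inputs": {"edges": str(edges_path), "nodes": str(nodes_path)},
        "stages": [],
        "outputs": [],
    }

    def _write_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                manifest["stages"].append({"name": name, "status": "failed",
                                           "error": str(exc)})
                _write_manifest()
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(
                {"name": name, "status": "ok",
                 "seconds": round(time.perf_counter() - t0, 3)}
            )
            return result

        return deco

    def declare(path):
        manifest["outputs"].append(str(path.relative_to(out)))
        return path

    graph, nodes = stage("read")(lambda: read_edgelist(edges_path, nodes_path))
    result = stage("analyze")(lambda: analyze(graph, nodes, config=cfg))

    def write_outputs():
        import pandas as pd

        pr = result.pagerank
        pd.DataFrame({"node_id": np.arange(graph.n_nodes), "P": pr.p, "K": pr.rank}).to_csv(
            declare(out / "pagerank.tsv"), sep="\t", index=False
        )
        save_reduced(result.reduced, out / "reduced")
        for f in sorted((out / "reduced").iterdir()):
            declare(f)
        pd.DataFrame(
            {
                "source": result.hidden.edges[:, 0],
                "target": result.hidden.edges[:, 1],
                "weight": result.hidden.weights,
            }
        ).to_csv(declare(out / "hidden_links.tsv"), sep="\t", index=False)
        declare(out / "hidden_meta.json").write_text(
            json.dumps(
                {
                    "cutoff": result.hidden.cutoff,
                    "lcc_ratio_direct": result.direct.lcc_ratio,
                    "lcc_ratio_hidden": result.hidden.lcc_ratio,
                    "n_edges": int(result.hidden.n_edges),
                },
                indent=2,
            )
        )
        write_clustering(result.clustering, declare(out / "communities.tsv"),
                         declare(out / "mcl_params.json"))
        rows = []
        for cid, (comm, lab) in enumerate(zip(result.clustering.communities, result.labels)):
            cs = set(comm.tolist())
            n_links = sum(
                1 for a, b in result.hidden.edges.tolist() if a in cs and b in cs
            )
            rows.append((cid, lab.label, len(comm), n_links, int(lab.self_labeled)))
        pd.DataFrame(
            rows, columns=["community_id", "label", "n_proteins", "n_hidden_links",
                           "self_labeled"]
        ).to_csv(declare(out / "community_map.tsv"), sep="\t", index=False)

    stage("write")(write_outputs)
    _write_manifest()
    manifest["outputs"].append("manifest.json")
    _write_manifest()
    return manifest


def simulate_to_dir(spec, out_dir, snapshot_pair: bool = False, **pair_kwargs) -> dict:
    """Write synthetic inputs (edge list, node table, ground truth) to a dir."""
    from .synthetic_data import generate_global_graph, generate_snapshot_pair, write_ground_truth

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    if snapshot_pair:
        g_old, n_old, t_old, g_new, n_new, t_new = generate_snapshot_pair(spec, **pair_kwargs)
        for tag, g, n, t in (("old", g_old, n_old, t_old), ("new", g_new, n_new, t_new)):
            write_edgelist(g, out / f"edges_{tag}.tsv")
            write_node_table(n, out / f"nodes_{tag}.tsv")
            write_ground_truth(t, out / f"truth_{tag}.tsv")
            written[tag] = {k: str(out / f"{k}_{tag}.tsv") for k in ("edges", "nodes", "truth")}
    else:
        graph, nodes, truth = generate_global_graph(spec)
        write_edgelist(graph, out / "edges.tsv")
        write_node_table(nodes, out / "nodes.tsv")
        write_ground_truth(truth, out / "truth.tsv")
        written = {k: str(out / f"{k}.tsv") for k in ("edges", "nodes", "truth")}
    return written


def recovery_ari(analysis: HiddenAnalysis, truth) -> float:
    """Adjusted Rand index of the recovered communities vs planted labels.

    Computed over the clustered nodes (proteins dropped by the cutoff or the
    minimum community size are not scored).
    """
    from sklearn.metrics import adjusted_rand_score

    pred = analysis.clustering.labels()
    ids = sorted(pred)
    return float(
        adjusted_rand_score(
            [truth.labels[v] for v in ids], [pred[v] for v in ids]
        )
    )
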