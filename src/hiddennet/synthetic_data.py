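"""Synthetic hyperlink graphs with planted protein communities.

The generator emulates the structure the hidden-link analysis assumes: a
sparse directed background graph (encyclopedia pages) containing a marked
"protein" subset organized into planted communities.  Each community owns
one or more background "topic" pages (hubs); members cite their hub and/or
are cited by it, creating the oriented length-2 protein -> topic -> protein
paths that the reduced Google matrix resolves into hidden links.  Direct
protein -> protein arcs inside a community mimic imported interaction lists
and carry a reciprocity excess (interaction lists tend to be symmetric),
while hub attachment is mostly one-directional, so hidden links end up far
less reciprocal than direct ones.

A perturbation model produces snapshot pairs: hub-incident arcs are re-drawn
within their community (topic pages are edited often and re-target which
members they cite), a smaller fraction of direct arcs is re-drawn, and
communities grow by a size factor — new members attach by the same rules.
Every draw comes from one seeded generator per call; no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graph_core import DirectedGraph, NodeTable


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the generator (defaults = the standard scenario)."""

    n_background: int = 2000
    n_communities: int = 12
    proteins_per_community: int = 10
    hubs_per_community: int = 1
    p_member_hub: float = 0.9        # protein participates with a given hub
    p_hub_reciprocal: float = 0.0    # both arc directions, else one oriented direction
    p_citer: float = 1.0             # one-directional member cites the hub (vs is cited)
    p_direct: float = 0.15           # intra-community interaction per unordered pair
    p_direct_reciprocal: float = 0.35  # drawn interaction gets both directions
    p_background_edge: float = 0.002
    p_cross: float = 0.01            # protein -> random background page
    preferential_attachment: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("p_member_hub", "p_hub_reciprocal", "p_citer", "p_direct",
                     "p_direct_reciprocal", "p_background_edge", "p_cross"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_background < self.n_communities * self.hubs_per_community:
            raise ValueError("not enough background nodes to host the hubs")

    @property
    def n_proteins(self) -> int:
        return self.n_communities * self.proteins_per_community

    @property
    def n_nodes(self) -> int:
        return self.n_background + self.n_proteins


@dataclass
class GroundTruth:
    """Planted labels: protein -> community, community -> hub pages."""

    labels: dict[int, int]
    hubs: dict[int, list[int]]
    hub_titles: dict[int, str]

    def label_array(self, node_ids) -> np.ndarray:
        return np.array([self.labels[int(v)] for v in node_ids], dtype=np.int64)


@dataclass
class _ArcGroups:
    """Generator bookkeeping: arcs by provenance, for snapshot perturbation."""

    background: list[tuple[int, int]] = field(default_factory=list)
    cross: list[tuple[int, int]] = field(default_factory=list)
    hub: list[tuple[int, int]] = field(default_factory=list)
    direct: list[tuple[int, int]] = field(default_factory=list)

    def all_arcs(self) -> np.ndarray:
        arcs = self.background + self.cross + self.hub + self.direct
        return np.array(arcs, dtype=np.int64).reshape(-1, 2)


def _draw_background(spec: SyntheticSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    n = spec.n_background
    if spec.preferential_attachment:
        # heavy-tail variant: out-degree ~ binomial, targets ~ degree-biased
        weights = 1.0 + rng.pareto(2.0, size=n)
        weights /= weights.sum()
        arcs = []
        k = rng.binomial(n - 1, spec.p_background_edge, size=n)
        for u in range(n):
            if k[u] == 0:
                continue
            targets = rng.choice(n, size=k[u], replace=False, p=weights)
            arcs.extend((u, int(t)) for t in targets if t != u)
        return arcs
    mask = rng.random((n, n)) < spec.p_background_edge
    np.fill_diagonal(mask, False)
    rows, cols = np.nonzero(mask)
    return list(zip(rows.tolist(), cols.tolist()))


def _attach_members(
    members: np.ndarray,
    hubs: list[int],
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Hub-incident arcs for a community, guaranteed non-empty per direction."""
    arcs: list[tuple[int, int]] = []
    for h in hubs:
        to_hub_exists = from_hub_exists = False
        for p in members.tolist():
            if rng.random() >= spec.p_member_hub:
                continue
            if rng.random() < spec.p_hub_reciprocal:
                arcs += [(p, h), (h, p)]
                to_hub_exists = from_hub_exists = True
            elif rng.random() < spec.p_citer:
                arcs.append((p, h))
                to_hub_exists = True
            else:
                arcs.append((h, p))
                from_hub_exists = True
        # every hub must mediate at least one oriented length-2 path
        if not to_hub_exists:
            arcs.append((int(members[0]), h))
        if not from_hub_exists:
            arcs.append((h, int(members[-1])))
    return arcs


def _draw_direct(
    members: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> list[tuple[int, int]]:
    arcs: list[tuple[int, int]] = []
    mem = members.tolist()
    for i, a in enumerate(mem):
        for b in mem[i + 1:]:
            if rng.random() >= spec.p_direct:
                continue
            if rng.random() < spec.p_direct_reciprocal:
                arcs += [(a, b), (b, a)]
            elif rng.random() < 0.5:
                arcs.append((a, b))
            else:
                arcs.append((b, a))
    return arcs


def _build(spec: SyntheticSpec, rng: np.random.Generator):
    groups = _ArcGroups()
    groups.background = _draw_background(spec, rng)
    hubs: dict[int, list[int]] = {}
    labels: dict[int, int] = {}
    hub_titles: dict[int, str] = {}
    members_of: dict[int, np.ndarray] = {}
    for c in range(spec.n_communities):
        hubs[c] = [c * spec.hubs_per_community + k for k in range(spec.hubs_per_community)]
        for h in hubs[c]:
            hub_titles[h] = f"Topic_{c}" if spec.hubs_per_community == 1 else f"Topic_{c}_{h}"
        start = spec.n_background + c * spec.proteins_per_community
        members = np.arange(start, start + spec.proteins_per_community)
        members_of[c] = members
        labels.update({int(p): c for p in members})
        groups.hub += _attach_members(members, hubs[c], spec, rng)
        groups.direct += _draw_direct(members, spec, rng)
    if spec.n_proteins and spec.p_cross > 0:
        # cross-citation noise targets generic background pages, never topic
        # hubs: hub citation is the planted signal, and letting noise arcs hit
        # another community's hub would plant spurious inter-community links
        n_hubs = spec.n_communities * spec.hubs_per_community
        pool = spec.n_background - n_hubs
        mask = rng.random((spec.n_proteins, pool)) < spec.p_cross
        rows, cols = np.nonzero(mask)
        groups.cross = list(zip((rows + spec.n_background).tolist(),
                                (cols + n_hubs).tolist()))
    truth = GroundTruth(labels=labels, hubs=hubs, hub_titles=hub_titles)
    return groups, truth, members_of


def _node_table(spec_like_n_bg: int, truth: GroundTruth, protein_ids: np.ndarray) -> NodeTable:
    n = spec_like_n_bg + len(protein_ids)
    titles = [f"Page_{i}" for i in range(spec_like_n_bg)]
    for h, t in truth.hub_titles.items():
        titles[h] = t
    rows = [{"node_id": i, "title": titles[i], "is_protein": False, "symbol": pd.NA}
            for i in range(spec_like_n_bg)]
    for p in protein_ids.tolist():
        c = truth.labels[p]
        rows.append({"node_id": p, "title": f"Protein_{c}_{p}", "is_protein": True,
                     "symbol": f"G{p}"})
    table = pd.DataFrame(rows)
    assert len(table) == n
    return NodeTable(table)


def generate_global_graph(spec: SyntheticSpec) -> tuple[DirectedGraph, NodeTable, GroundTruth]:
    """Draw one synthetic global graph; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    groups, truth, _ = _build(spec, rng)
    arcs = groups.all_arcs()
    graph = DirectedGraph.from_edges(spec.n_nodes, arcs, log_drops=False)
    protein_ids = np.arange(spec.n_background, spec.n_nodes)
    nodes = _node_table(spec.n_background, truth, protein_ids)
    if spec.n_communities > 0:
        prot_mask = np.zeros(spec.n_nodes, dtype=bool)
        prot_mask[protein_ids] = True
        if not (prot_mask[graph.edges[:, 0]] | prot_mask[graph.edges[:, 1]]).any():
            raise ValueError("spec yields a graph with zero protein arcs")
    return graph, nodes, truth


def generate_snapshot_pair(
    spec: SyntheticSpec,
    rewire_hub_frac: float = 0.3,
    rewire_direct_frac: float = 0.05,
    growth: float = 1.2,
):
    """An (old, new) snapshot pair with hub churn, direct churn and growth.

    Returns ``(graph_old, nodes_old, truth_old, graph_new, nodes_new,
    truth_new)``.  The old snapshot is exactly ``generate_global_graph(spec)``.
    """
    for name, v in (("rewire_hub_frac", rewire_hub_frac),
                    ("rewire_direct_frac", rewire_direct_frac)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if growth < 1.0:
        raise ValueError("growth must be >= 1")
    rng = np.random.default_rng(spec.seed)
    groups, truth, members_of = _build(spec, rng)
    graph_old = DirectedGraph.from_edges(spec.n_nodes, groups.all_arcs(), log_drops=False)
    protein_ids_old = np.arange(spec.n_background, spec.n_nodes)
    nodes_old = _node_table(spec.n_background, truth, protein_ids_old)

    rng2 = np.random.default_rng(spec.seed + 1_000_003)
    hub_of: dict[int, int] = {h: c for c, hs in truth.hubs.items() for h in hs}

    new_hub: list[tuple[int, int]] = []
    for a, b in groups.hub:
        if rng2.random() < rewire_hub_frac:
            h = a if a in hub_of else b
            members = members_of[hub_of[h]]
            p = int(rng2.choice(members))
            # re-drawn arc keeps the attachment direction statistics
            if rng2.random() < spec.p_hub_reciprocal:
                new_hub += [(p, h), (h, p)]
            elif rng2.random() < spec.p_citer:
                new_hub.append((p, h))
            else:
                new_hub.append((h, p))
        else:
            new_hub.append((a, b))
    new_direct: list[tuple[int, int]] = []
    for a, b in groups.direct:
        if rng2.random() < rewire_direct_frac:
            members = members_of[truth.labels[a]]
            x, y = rng2.choice(members, size=2, replace=False)
            new_direct.append((int(x), int(y)))
        else:
            new_direct.append((a, b))

    # growth: append new members per community, attached by the same rules
    labels_new = dict(truth.labels)
    next_id = spec.n_nodes
    members_new: dict[int, np.ndarray] = {}
    for c in range(spec.n_communities):
        n_add = int(round((growth - 1.0) * len(members_of[c])))
        added = np.arange(next_id, next_id + n_add)
        next_id += n_add
        labels_new.update({int(p): c for p in added})
        members_new[c] = np.concatenate([members_of[c], added])
        if n_add == 0:
            continue
        for h in truth.hubs[c]:
            for p in added.tolist():
                if rng2.random() >= spec.p_member_hub:
                    continue
                if rng2.random() < spec.p_hub_reciprocal:
                    new_hub += [(p, h), (h, p)]
                elif rng2.random() < spec.p_citer:
                    new_hub.append((p, h))
                else:
                    new_hub.append((h, p))
        for p in added.tolist():
            for q in members_of[c].tolist():
                if rng2.random() >= spec.p_direct:
                    continue
                if rng2.random() < spec.p_direct_reciprocal:
                    new_direct += [(p, q), (q, p)]
                elif rng2.random() < 0.5:
                    new_direct.append((p, q))
                else:
                    new_direct.append((q, p))
        if spec.p_cross > 0:
            n_hubs = spec.n_communities * spec.hubs_per_community
            pool = spec.n_background - n_hubs
            mask = rng2.random((n_add, pool)) < spec.p_cross
            rows, cols = np.nonzero(mask)
            groups.cross += list(zip((rows + int(added[0])).tolist(),
                                     (cols + n_hubs).tolist()))

    truth_new = GroundTruth(labels=labels_new, hubs=truth.hubs, hub_titles=truth.hub_titles)
    arcs_new = np.array(
        groups.background + groups.cross + new_hub + new_direct, dtype=np.int64
    ).reshape(-1, 2)
    graph_new = DirectedGraph.from_edges(next_id, arcs_new, log_drops=False)
    protein_ids_new = np.concatenate(
        [protein_ids_old, np.arange(spec.n_nodes, next_id)]
    )
    nodes_new = _node_table(spec.n_background, truth_new, protein_ids_new)
    return graph_old, nodes_old, truth, graph_new, nodes_new, truth_new


def planted_gene_sets(
    truth: GroundTruth, nodes: NodeTable, n_decoys: int = 5,
    decoy_size: int = 15, seed: int = 0,
) -> dict[str, set[str]]:
    """Gene sets matching the planted communities, plus random decoy sets."""
    sym = nodes.symbol_map()
    sets: dict[str, set[str]] = {}
    for c in sorted(set(truth.labels.values())):
        sets[f"planted_community_{c}"] = {
            sym[p] for p, lab in truth.labels.items() if lab == c and p in sym
        }
    rng = np.random.default_rng(seed)
    universe = sorted(sym.values())
    for d in range(n_decoys):
        sets[f"decoy_{d}"] = set(rng.choice(universe, size=min(decoy_size, len(universe)),
                                            replace=False))
    return sets


def write_ground_truth(truth: GroundTruth, path) -> None:
    pd.DataFrame(
        sorted(truth.labels.items()), columns=["node_id", "community_id"]
    ).to_csv(path, sep="\t", index=False)


def default_spec(**overrides) -> SyntheticSpec:
    return replace(SyntheticSpec(), **overrides) if overrides else SyntheticSpec()
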