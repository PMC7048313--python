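"""Two-snapshot comparison: link persistence, rank folds, community matching.

Persistence is the fraction of the OLD snapshot's arcs (restricted to nodes
present in both snapshots) still present in the new one.  PageRank change is
measured on the rank index K (smaller = more central): a protein "improves"
when K_old / K_new exceeds the fold threshold.  Communities of the two
snapshots are matched by reciprocal-best Jaccard index over shared nodes,
with a minimum intersection (default 3); ties at a row or column maximum are
conservatively left unmatched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


def _restrict(arcs, shared: set[int], unordered: bool) -> set[tuple[int, int]]:
    out = set()
    for a, b in map(tuple, np.asarray(arcs, dtype=np.int64).reshape(-1, 2).tolist()):
        if a in shared and b in shared:
            out.add((min(a, b), max(a, b)) if unordered else (a, b))
    return out


def link_persistence(old_arcs, new_arcs, shared_nodes, unordered: bool = False) -> float:
    """|old ∩ new| / |old| over arcs among nodes shared by both snapshots."""
    shared = set(map(int, shared_nodes))
    old = _restrict(old_arcs, shared, unordered)
    if not old:
        raise ValueError("no old arcs among the shared nodes; persistence undefined")
    new = _restrict(new_arcs, shared, unordered)
    return len(old & new) / len(old)


@dataclass
class RankFoldResult:
    improved: list[int]        # rank got smaller by more than `fold`
    worsened: list[int]
    folds: dict[int, float]    # node -> K_old / K_new
    n_excluded: int            # nodes missing from either snapshot


def rank_fold_changes(
    ranks_old: dict[int, int],
    ranks_new: dict[int, int],
    fold: float = 2.0,
) -> RankFoldResult:
    """Split shared nodes into >fold improved / worsened sets on rank index K."""
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    shared = sorted(set(ranks_old) & set(ranks_new))
    n_excluded = len(set(ranks_old) ^ set(ranks_new))
    if n_excluded:
        logger.info("%d node(s) missing from one snapshot, excluded", n_excluded)
    improved, worsened, folds = [], [], {}
    for v in shared:
        ko, kn = ranks_old[v], ranks_new[v]
        folds[v] = ko / kn
        if ko / kn > fold:
            improved.append(v)
        elif kn / ko > fold:
            worsened.append(v)
    return RankFoldResult(improved=improved, worsened=worsened, folds=folds,
                          n_excluded=n_excluded)


@dataclass
class CommunityMatch:
    old_index: int
    new_index: int
    jaccard: float
    intersection: int
    size_old: int
    size_new: int


def match_communities(
    clusters_old,
    clusters_new,
    min_intersection: int = 3,
    shared_nodes=None,
) -> list[CommunityMatch]:
    """Reciprocal-best Jaccard matching between two community sets.

    The Jaccard index is computed over shared nodes (defaults to the union of
    all members).  A pair matches iff it is both the row and the column
    maximum of the Jaccard matrix and intersects in at least
    ``min_intersection`` shared members; ties at a maximum yield no match.
    Reported sizes are full community sizes (including unshared members).
    """
    if min_intersection < 1:
        raise ValueError("min_intersection must be >= 1")
    old_sets = clusters_old.as_sets() if hasattr(clusters_old, "as_sets") else [set(c) for c in clusters_old]
    new_sets = clusters_new.as_sets() if hasattr(clusters_new, "as_sets") else [set(c) for c in clusters_new]
    if not old_sets or not new_sets:
        raise ValueError("cannot match an empty clustering")
    if shared_nodes is not None:
        shared = set(map(int, shared_nodes))
        old_r = [c & shared for c in old_sets]
        new_r = [c & shared for c in new_sets]
    else:
        old_r, new_r = old_sets, new_sets
    J = np.zeros((len(old_r), len(new_r)))
    inter = np.zeros_like(J, dtype=np.int64)
    for i, a in enumerate(old_r):
        for j, b in enumerate(new_r):
            u = len(a | b)
            inter[i, j] = len(a & b)
            J[i, j] = inter[i, j] / u if u else 0.0
    matches = []
    for i in range(J.shape[0]):
        row = J[i]
        j = int(np.argmax(row))
        if row[j] == 0 or (row == row[j]).sum() > 1:
            continue  # no signal, or tied row maximum
        col = J[:, j]
        if (col == col.max()).sum() > 1 or int(np.argmax(col)) != i:
            continue
        if inter[i, j] < min_intersection:
            continue
        matches.append(
            CommunityMatch(
                old_index=i, new_index=j, jaccard=float(J[i, j]),
                intersection=int(inter[i, j]),
                size_old=len(old_sets[i]), size_new=len(new_sets[j]),
            )
        )
    return matches


def snapshot_report(persistence: dict, rank_folds: RankFoldResult,
                    matches: list[CommunityMatch]) -> dict:
    """JSON-ready summary of a two-snapshot comparison."""
    return {
        "persistence": persistence,
        "n_improved": len(rank_folds.improved),
        "n_worsened": len(rank_folds.worsened),
        "matches": [
            {
                "old": m.old_index, "new": m.new_index,
                "jaccard": m.jaccard, "intersection": m.intersection,
                "size_old": m.size_old, "size_new": m.size_new,
            }
            for m in matches
        ],
    }
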