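"""Reference-network comparison statistics and local gene-set enrichment.

Wiki-derived arc sets are compared against curated interaction databases on
unordered pairs of matched gene symbols (curated databases mix directed and
undirected semantics; a directed mode is available behind a flag).  Community
enrichment is a local hypergeometric test with Benjamini-Hochberg correction,
filtered by minimum overlap (default 5 genes) and a q-value ceiling
(default 1e-8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

REFERENCE_COLUMNS = ["symbol_a", "symbol_b", "type"]


@dataclass(frozen=True)
class ReferenceNetwork:
    """Curated interaction network: (symbol_a, symbol_b, interaction type)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REFERENCE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"reference network missing columns: {missing}")
        if (self.frame[["symbol_a", "symbol_b"]] == "").any().any():
            raise ValueError("reference network contains empty symbols")

    def symbols(self) -> set[str]:
        return set(self.frame["symbol_a"]) | set(self.frame["symbol_b"])

    def pairs(self, types: list[str] | None = None, directed: bool = False) -> set[tuple[str, str]]:
        df = self.frame if types is None else self.frame[self.frame["type"].isin(types)]
        if directed:
            return set(zip(df["symbol_a"], df["symbol_b"]))
        return {tuple(sorted(p)) for p in zip(df["symbol_a"], df["symbol_b"])}


def read_reference_tsv(path) -> ReferenceNetwork:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:3]) != REFERENCE_COLUMNS:
        df.columns = REFERENCE_COLUMNS[: len(df.columns)]
    return ReferenceNetwork(df)


def _as_pairs(arcs, directed: bool) -> set[tuple[str, str]]:
    pairs = set()
    for a, b in arcs:
        if a == b:
            continue
        pairs.add((a, b) if directed else tuple(sorted((a, b))))
    return pairs


@dataclass
class OverlapResult:
    n_common_symbols: int
    n_wiki: int
    n_ref: int
    n_matched: int
    p_value: float
    table: tuple


def overlap_and_fisher(
    wiki_arcs,
    ref: ReferenceNetwork,
    universe_n: int | None = None,
    directed: bool = False,
) -> OverlapResult:
    """Matched-link counts and a one-sided Fisher exact test.

    The null model is that any two proteins of the matched set could be
    connected: the universe is all unordered (or ordered, with
    ``directed=True``) pairs over the common symbol set, and the 2x2 table is
    {matched, wiki-only, ref-only, neither}.
    """
    wiki_symbols = {s for pair in wiki_arcs for s in pair}
    common = wiki_symbols & ref.symbols()
    if not common:
        raise ValueError("no symbols shared between the wiki network and the reference")
    n = universe_n if universe_n is not None else len(common)
    universe = n * (n - 1) if directed else n * (n - 1) // 2
    wiki = {p for p in _as_pairs(wiki_arcs, directed) if p[0] in common and p[1] in common}
    refp = {
        p for p in ref.pairs(directed=directed) if p[0] in common and p[1] in common
    }
    a = len(wiki & refp)
    b = len(wiki - refp)
    c = len(refp - wiki)
    d = universe - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return OverlapResult(
        n_common_symbols=len(common),
        n_wiki=len(wiki),
        n_ref=len(refp),
        n_matched=a,
        p_value=float(p),
        table=(a, b, c, d),
    )


def degree_correlation(arcs_a, arcs_b, shared_nodes) -> float:
    """Pearson correlation of total node degrees across two networks."""
    shared = list(shared_nodes)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared nodes")

    def degrees(arcs):
        deg: dict = {}
        for a, b in arcs:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg

    da, db = degrees(arcs_a), degrees(arcs_b)
    x = np.array([da.get(v, 0) for v in shared], dtype=float)
    y = np.array([db.get(v, 0) for v in shared], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degree vector is constant; correlation undefined")
    return float(stats.pearsonr(x, y)[0])


def relative_type_fractions(
    wiki_arcs,
    ref: ReferenceNetwork,
    wiki_symbols: set[str] | None = None,
    directed: bool = False,
) -> pd.DataFrame:
    """Per interaction type t: f_t = I_t^wiki / I_t^ref and its normalization.

    The reference is first limited to symbols shared with the wiki network.
    Types without any reference link among common symbols are dropped (they
    carry no denominator); the relative fractions of the retained types sum
    to one.
    """
    if wiki_symbols is None:
        wiki_symbols = {s for pair in wiki_arcs for s in pair}
    common = wiki_symbols & ref.symbols()
    wiki = {p for p in _as_pairs(wiki_arcs, directed) if p[0] in common and p[1] in common}
    rows = []
    for t in sorted(ref.frame["type"].unique()):
        ref_pairs = {
            p
            for p in ref.pairs(types=[t], directed=directed)
            if p[0] in common and p[1] in common
        }
        if not ref_pairs:
            continue
        matched = len(wiki & ref_pairs)
        rows.append((t, len(ref_pairs), matched, matched / len(ref_pairs)))
    if not rows:
        raise ValueError("no interaction type has reference links among common symbols")
    df = pd.DataFrame(rows, columns=["type", "I_ref", "I_wiki", "f"])
    total = df["f"].sum()
    df["f_rel"] = df["f"] / total if total > 0 else np.nan
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (name, description, then symbols)."""
    from gseapy.parser import read_gmt as _read_gmt  # lazy: heavy import chain

    sets = {name: {g for g in genes if g} for name, genes in _read_gmt(str(path)).items()}
    if not sets:
        raise ValueError(f"empty gene-set file: {path}")
    return sets


def hypergeom_enrichment_p(k: int, universe: int, set_size: int, query_size: int) -> float:
    """Upper-tail hypergeometric probability of an overlap of at least k."""
    return float(stats.hypergeom.sf(k - 1, universe, set_size, query_size))


def enrich_communities(
    community_symbols: dict[int, set[str]],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    min_overlap: int = 5,
    q_max: float = 1e-8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hypergeometric enrichment of each community against each gene set.

    Gene sets and communities are intersected with the universe first;
    BH q-values are computed across all gene sets within one community.
    Returns ``(all_results, summary)`` where the summary keeps rows with
    overlap >= ``min_overlap`` and q <= ``q_max``.
    """
    if not gene_sets:
        raise ValueError("empty gene-set collection")
    M = len(universe)
    records = []
    for cid, members in sorted(community_symbols.items()):
        query = set(members) & universe
        n_unmapped = len(set(members)) - len(query)
        ps, metas = [], []
        for term, genes in sorted(gene_sets.items()):
            gs = set(genes) & universe
            k = len(query & gs)
            p = hypergeom_enrichment_p(k, M, len(gs), len(query)) if gs else 1.0
            ps.append(p)
            metas.append((term, k, len(gs)))
        qs = multipletests(ps, method="fdr_bh")[1] if ps else []
        for (term, k, size), p, q in zip(metas, ps, qs):
            records.append(
                {
                    "community_id": cid,
                    "term": term,
                    "overlap_k": k,
                    "set_size": size,
                    "community_size": len(query),
                    "universe_size": M,
                    "n_unmapped": n_unmapped,
                    "p": p,
                    "q": q,
                }
            )
    results = pd.DataFrame.from_records(records)
    summary = results[
        (results["overlap_k"] >= min_overlap) & (results["q"] <= q_max)
    ].reset_index(drop=True)
    return results, summary


def community_symbol_sets(clustering, nodes) -> dict[int, set[str]]:
    """Map each community to the gene symbols of its members (unmapped dropped)."""
    sym = nodes.symbol_map()
    return {
        cid: {sym[int(v)] for v in comm if int(v) in sym}
        for cid, comm in enumerate(clustering.communities)
    }
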