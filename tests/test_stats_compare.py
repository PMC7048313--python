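import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from hiddennet.stats_compare import (
    ReferenceNetwork,
    community_symbol_sets,
    degree_correlation,
    enrich_communities,
    hypergeom_enrichment_p,
    overlap_and_fisher,
    read_gmt,
    read_reference_tsv,
    relative_type_fractions,
)


def ref_net(pairs, types=None):
    types = types or ["binds"] * len(pairs)
    return ReferenceNetwork(
        pd.DataFrame(
            {"symbol_a": [p[0] for p in pairs], "symbol_b": [p[1] for p in pairs],
             "type": types}
        )
    )


def enumerate_fisher_tail(universe, n_wiki, n_ref, overlap):
    """Exact one-sided tail by summation of hypergeometric point masses."""
    total = Fraction(0)
    for k in range(overlap, min(n_wiki, n_ref) + 1):
        total += Fraction(
            math.comb(n_ref, k) * math.comb(universe - n_ref, n_wiki - k),
            math.comb(universe, n_wiki),
        )
    return float(total)


class TestFisher:
    def test_full_overlap_point_mass(self):
        # 20-pair universe, wiki and ref each pick the same 10 pairs:
        # p = 1 / C(20, 10)
        symbols = [f"G{i}" for i in range(7)]  # C(7,2) = 21 pairs; use 20 via universe_n? keep exact:
        pairs = list(itertools.combinations(symbols, 2))[:10]
        wiki = pairs
        ref = ref_net(pairs)
        res = overlap_and_fisher(wiki, ref, universe_n=None)
        # universe from the 7 common symbols is C(7,2)=21 pairs
        expected = enumerate_fisher_tail(21, 10, 10, 10)
        assert res.p_value == pytest.approx(expected, rel=1e-9)
        assert res.n_matched == 10

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        symbols = [f"G{i}" for i in range(10)]
        all_pairs = list(itertools.combinations(symbols, 2))  # 45-pair universe
        wiki = [all_pairs[i] for i in rng.choice(45, size=12, replace=False)]
        refp = [all_pairs[i] for i in rng.choice(45, size=15, replace=False)]
        res = overlap_and_fisher(wiki, ref_net(refp), universe_n=10)
        expected = enumerate_fisher_tail(45, res.n_wiki, res.n_ref, res.n_matched)
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_no_enrichment_p_near_one(self):
        # one wiki pair, one disjoint reference pair over a sizeable universe
        res = overlap_and_fisher([("A", "B")], ref_net([("A", "C")]), universe_n=100)
        assert res.n_matched == 0
        assert res.p_value > 0.4

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            overlap_and_fisher([("A", "B")], ref_net([("X", "Y")]))


class TestDegreeCorrelation:
    def test_identical_networks(self):
        arcs = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C")]  # degrees 3,2,2,1
        assert degree_correlation(arcs, arcs, ["A", "B", "C", "D"]) == pytest.approx(1.0)

    def test_anticorrelated_degrees(self):
        # degrees over A,B,C: network a = (1,2,3), network b = (3,2,1)
        a = [("A", "X"), ("B", "X"), ("B", "Y"), ("C", "X"), ("C", "Y"), ("C", "Z")]
        b = [("C", "X"), ("B", "X"), ("B", "Y"), ("A", "X"), ("A", "Y"), ("A", "Z")]
        assert degree_correlation(a, b, ["A", "B", "C"]) == pytest.approx(-1.0)

    def test_hand_evaluated_pearson(self):
        # degrees (1,2,3) vs (1,2,4): closed form vs brute-force sums
        a = [("A", "X"), ("B", "X"), ("B", "Y"), ("C", "X"), ("C", "Y"), ("C", "Z")]
        b = [("A", "X"), ("B", "X"), ("B", "Y"), ("C", "X"), ("C", "Y"), ("C", "Z"),
             ("C", "W")]
        x, y = np.array([1, 2, 3.0]), np.array([1, 2, 4.0])
        expected = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        r = degree_correlation(a, b, ["A", "B", "C"])
        assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_degrees_rejected(self):
        a = [("A", "B"), ("B", "C"), ("C", "A")]  # every degree is 2
        with pytest.raises(ValueError, match="constant"):
            degree_correlation(a, a, ["A", "B", "C"])

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError, match="3 shared"):
            degree_correlation([("A", "B")], [("A", "B")], ["A", "B"])


class TestTypeFractions:
    def test_equal_fractions_split_evenly(self):
        ref = ref_net(
            [("A", "B"), ("C", "D"), ("A", "C"), ("B", "D")],
            types=["t1", "t1", "t2", "t2"],
        )
        wiki = [("A", "B"), ("A", "C")]
        df = relative_type_fractions(wiki, ref, wiki_symbols={"A", "B", "C", "D"})
        assert df.f.tolist() == [0.5, 0.5]
        assert df.f_rel.tolist() == [0.5, 0.5]

    def test_three_to_one_ratio(self):
        # wiki matches 3/5 of type t1 but only 1/5 of type t2
        ref = ref_net(
            [("A", "B"), ("C", "D"), ("E", "F"), ("G", "H"), ("I", "J"),
             ("A", "C"), ("B", "D"), ("E", "G"), ("F", "H"), ("I", "A")],
            types=["t1"] * 5 + ["t2"] * 5,
        )
        wiki = [("A", "B"), ("C", "D"), ("E", "F"), ("A", "C")]
        df = relative_type_fractions(wiki, ref, wiki_symbols=set("ABCDEFGHIJ"))
        f = dict(zip(df.type, df.f))
        assert f == {"t1": 0.6, "t2": 0.2}
        frel = dict(zip(df.type, df.f_rel))
        assert frel["t1"] == pytest.approx(0.75) and frel["t2"] == pytest.approx(0.25)
        assert df.f_rel.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_type_normalizes_to_one(self):
        ref = ref_net([("A", "B")])
        df = relative_type_fractions([("A", "B")], ref, wiki_symbols={"A", "B"})
        assert df.f_rel.tolist() == [1.0]

    def test_empty_type_dropped(self):
        ref = ref_net([("A", "B"), ("X", "Y")], types=["t1", "t2"])
        df = relative_type_fractions([("A", "B")], ref, wiki_symbols={"A", "B"})
        assert df.type.tolist() == ["t1"]

    def test_all_types_empty_rejected(self):
        ref = ref_net([("X", "Y")])
        with pytest.raises(ValueError, match="no interaction type"):
            relative_type_fractions([("A", "B")], ref, wiki_symbols={"A", "B"})


class TestEnrichment:
    def test_identical_set_exact_rational_point_mass(self):
        universe = {f"G{i}" for i in range(1000)}
        genes = {f"G{i}" for i in range(20)}
        results, summary = enrich_communities(
            {0: genes}, {"set20": genes, "other": {f"G{i}" for i in range(500, 540)}},
            universe,
        )
        row = results[results.term == "set20"].iloc[0]
        expected = float(Fraction(1, math.comb(1000, 20)))
        assert row.p == pytest.approx(expected, rel=1e-9)
        assert summary.term.tolist() == ["set20"]

    def test_min_overlap_filter(self):
        universe = {f"G{i}" for i in range(100)}
        comm = {f"G{i}" for i in range(4)}
        results, summary = enrich_communities(
            {0: comm}, {"s": comm}, universe, min_overlap=5, q_max=1.0
        )
        assert results.iloc[0].overlap_k == 4
        assert summary.empty  # overlap 4 < 5 excluded regardless of p

    def test_bh_q_monotone_in_sorted_p(self):
        rng = np.random.default_rng(0)
        universe = {f"G{i}" for i in range(200)}
        comm = {f"G{i}" for i in range(20)}
        sets = {
            f"s{k}": set(rng.choice(sorted(universe), size=15, replace=False))
            for k in range(10)
        }
        results, _ = enrich_communities({0: comm}, sets, universe, q_max=1.0)
        r = results.sort_values("p")
        assert (r.q.to_numpy()[1:] >= r.q.to_numpy()[:-1] - 1e-15).all()
        assert (results.q >= results.p - 1e-15).all()

    def test_empty_gene_sets_rejected(self):
        with pytest.raises(ValueError):
            enrich_communities({0: {"A"}}, {}, {"A"})

    def test_planted_communities_recovered_as_top_terms(self, default_setup, default_analysis):
        from hiddennet.synthetic_data import planted_gene_sets

        _, _, nodes, truth = default_setup
        res = default_analysis
        sets = planted_gene_sets(truth, nodes)
        universe = set(nodes.symbol_map().values())
        comm_syms = community_symbol_sets(res.clustering, nodes)
        results, _ = enrich_communities(comm_syms, sets, universe, q_max=1.0)
        top_hits = 0
        for cid, grp in results.groupby("community_id"):
            top = grp.sort_values(["p", "term"]).iloc[0]
            members = comm_syms[cid]
            planted = max(sets, key=lambda t: len(sets[t] & members))
            top_hits += top.term == planted
        assert top_hits >= 0.9 * len(comm_syms)


class TestIO:
    def test_read_reference(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text("symbol_a\tsymbol_b\ttype\nA\tB\tbinds\n")
        ref = read_reference_tsv(p)
        assert ref.pairs() == {("A", "B")}

    def test_read_gmt(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("set1\tdesc\tA\tB\tC\nset2\tdesc\tD\n")
        sets = read_gmt(p)
        assert sets["set1"] == {"A", "B", "C"}
        assert sets["set2"] == {"D"}
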