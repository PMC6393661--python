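"""Hypergeometric over-representation: enumeration oracles and BH behaviour."""

import math

import numpy as np
import pandas as pd
import pytest

from lnctrans import (
    GeneSetCollection,
    annotate_lncrna,
    enrich,
    fold_enrichment,
    hypergeom_upper_tail,
)


def upper_tail_by_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) as an exact integer-combinatorics sum (independent oracle)."""
    total = math.comb(N, n)
    hits = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
        if n - j <= N - K
    )
    return hits / total


class TestHypergeomUpperTail:
    def test_k_zero_is_exactly_one(self):
        assert hypergeom_upper_tail(0, 5, 4, 20) == 1.0

    def test_frozen_enumeration_value(self):
        # 0.24871 from exhaustive enumeration of all C(20,4) draws
        assert upper_tail_by_enumeration(2, 5, 4, 20) == pytest.approx(0.24871, abs=5e-6)
        assert hypergeom_upper_tail(2, 5, 4, 20) == pytest.approx(
            upper_tail_by_enumeration(2, 5, 4, 20), abs=1e-12
        )

    def test_maximal_overlap_is_point_mass(self):
        for N in (10, 18, 25):
            for K, n in [(4, 6), (7, 7), (3, 9)]:
                k = min(n, K)
                assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                    upper_tail_by_enumeration(k, K, n, N), abs=1e-12
                )

    def test_matches_enumeration_on_small_grid(self):
        for N in range(2, 16):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for k in range(0, min(n, K) + 1):
                        assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                            upper_tail_by_enumeration(k, K, n, N), abs=1e-12
                        )

    def test_pmf_sums_to_one(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            N = int(rng.integers(2, 60))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            lo = max(0, n + K - N)
            total = sum(
                hypergeom_upper_tail(k, K, n, N)
                - (hypergeom_upper_tail(k + 1, K, n, N) if k + 1 <= min(n, K) else 0.0)
                for k in range(lo, min(n, K) + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 3, 4, 20)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 30, 4, 20)


class TestFoldEnrichment:
    @pytest.mark.parametrize(
        "k,K,n,N,expected",
        [(1, 5, 4, 20, 1.0), (2, 5, 4, 20, 2.0), (4, 20, 4, 20, 1.0), (0, 5, 4, 20, 0.0)],
    )
    def test_hand_values(self, k, K, n, N, expected):
        assert fold_enrichment(k, K, n, N) == pytest.approx(expected)

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            fold_enrichment(1, 0, 4, 20)


@pytest.fixture()
def collection():
    genes = [f"g{i}" for i in range(60)]
    return GeneSetCollection(
        sets={
            "A": ("set A", frozenset(genes[0:10])),
            "B": ("set B", frozenset(genes[10:20])),
            "C": ("set C", frozenset(genes[20:35])),
        },
        universe=frozenset(genes),
    )


class TestEnrich:
    def test_perfect_overlap_ranks_first(self, collection):
        res = enrich(collection.members("A"), collection)
        assert res.iloc[0]["set_id"] == "A"
        assert res.iloc[0]["p"] == res["p"].min()
        assert res.iloc[0]["significant"]

    def test_empty_harmonized_query_raises(self, collection):
        with pytest.raises(ValueError):
            enrich({"not_a_gene"}, collection)

    def test_p_matches_enumeration(self, collection):
        res = enrich([f"g{i}" for i in range(5, 17)], collection)
        for row in res.itertuples():
            assert row.p == pytest.approx(
                upper_tail_by_enumeration(row.k, row.K, row.n, row.N), abs=1e-12
            )

    def test_universe_gene_removal_only_acts_through_N(self, collection):
        # drop a gene outside every set and outside the query
        smaller = GeneSetCollection(
            sets=dict(collection.sets),
            universe=collection.universe - {"g59"},
        )
        query = [f"g{i}" for i in range(5, 15)]
        res_big = enrich(query, collection).set_index("set_id")
        res_small = enrich(query, smaller).set_index("set_id")
        for sid in res_big.index:
            kb, ks = res_big.loc[sid], res_small.loc[sid]
            assert kb["k"] == ks["k"] and kb["K"] == ks["K"] and kb["n"] == ks["n"]
            assert ks["N"] == kb["N"] - 1
            assert ks["p"] == pytest.approx(
                upper_tail_by_enumeration(int(ks["k"]), int(ks["K"]), int(ks["n"]), int(ks["N"])),
                abs=1e-12,
            )

    def test_null_type_one_rate_calibrated(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(500)]
        coll = GeneSetCollection(
            sets={f"S{j}": ("d", frozenset(rng.choice(genes, 25, replace=False)))
                  for j in range(5)},
            universe=frozenset(genes),
        )
        hits = trials = 0
        for _ in range(200):
            query = rng.choice(genes, 20, replace=False)
            res = enrich(query, coll)
            hits += int((res["p"] < 0.05).sum())
            trials += len(res)
        frac = hits / trials
        sd = math.sqrt(0.05 * 0.95 / trials)
        # the hypergeometric test is discrete, hence conservative: the
        # realized type-I rate must stay at or below nominal, never above
        assert frac < 0.05 + 2.576 * sd
        assert frac > 0.0

    def test_bh_properties(self, collection):
        res = enrich([f"g{i}" for i in range(3, 24)], collection)
        assert (res["q"] >= res["p"] - 1e-15).all()
        by_p = res.sort_values("p")
        assert by_p["q"].is_monotonic_increasing


class TestAnnotateLncrna:
    def test_regulon_exact_coexpression_top_ranked(self, collection):
        edges = pd.DataFrame(
            {"lncrna_id": "L1", "mrna_id": sorted(collection.members("B")),
             "r": 0.9, "p": 0.001, "n": 6}
        )
        res = annotate_lncrna("L1", edges, collection)
        assert res.iloc[0]["set_id"] == "B"
        assert res.iloc[0]["significant"]

    def test_no_edges_gives_empty_annotation(self, collection, caplog):
        edges = pd.DataFrame(columns=["lncrna_id", "mrna_id", "r", "p", "n"])
        with caplog.at_level("WARNING", logger="lnctrans"):
            res = annotate_lncrna("L9", edges, collection)
        assert res.empty
        assert "L9" in caplog.text

    def test_single_gene_outside_sets_not_significant(self, collection):
        edges = pd.DataFrame(
            {"lncrna_id": ["L1"], "mrna_id": ["g59"], "r": [0.9], "p": [0.01], "n": [6]}
        )
        res = annotate_lncrna("L1", edges, collection)
        assert not res["significant"].any()
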