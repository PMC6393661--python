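"""Pair scoring, top-100/10 selection, triad expansion and network assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from lnctrans import (
    GeneSetCollection,
    assemble_network,
    build_triads,
    coexpression_pairs,
    hypergeom_upper_tail,
    score_pairs,
    select_pairs,
)
from lnctrans.trans_network import TransTriad, audit_network


def _edges(pairs):
    return pd.DataFrame(
        [{"lncrna_id": l, "mrna_id": m, "r": r, "p": p, "n": 6} for l, m, r, p in pairs]
    )


@pytest.fixture()
def regulons20():
    genes = [f"g{i}" for i in range(20)]
    return GeneSetCollection(
        sets={
            "TF1": ("r1", frozenset(genes[0:5])),
            "TF2": ("r2", frozenset(genes[5:10])),
        },
        universe=frozenset(genes),
    )


class TestScorePairs:
    def test_matching_regulon_dominates(self, regulons20):
        edges = _edges([("L1", f"g{i}", 0.9, 0.001) for i in range(5)])
        pairs = score_pairs(edges, regulons20, regulons20.universe)
        assert pairs.iloc[0]["tf_id"] == "TF1"
        assert pairs.iloc[0]["p"] < pairs.iloc[1]["p"]

    def test_p_matches_enumeration_oracle(self, regulons20):
        edges = _edges(
            [("L1", f"g{i}", 0.8, 0.01) for i in (0, 1, 5, 11)]
            + [("L2", f"g{i}", 0.8, 0.01) for i in (2, 3, 4, 6, 12)]
        )
        pairs = score_pairs(edges, regulons20, regulons20.universe)
        for row in pairs.itertuples():
            total = math.comb(row.N, row.n)
            brute = sum(
                math.comb(row.K, j) * math.comb(row.N - row.K, row.n - j)
                for j in range(row.k, min(row.n, row.K) + 1)
                if row.n - j <= row.N - row.K
            ) / total
            assert row.p == pytest.approx(brute, abs=1e-12)

    def test_lncrna_without_universe_genes_skipped(self, regulons20):
        edges = _edges([("L1", "outside", 0.9, 0.001)])
        with pytest.raises(ValueError):
            # the only lncRNA contributes nothing -> empty result is fine,
            # but empty *inputs* are the error condition
            score_pairs(pd.DataFrame(columns=edges.columns), regulons20,
                        regulons20.universe)
        pairs = score_pairs(edges, regulons20, regulons20.universe)
        assert pairs.empty

    def test_empty_universe_raises(self, regulons20):
        edges = _edges([("L1", "g0", 0.9, 0.001)])
        with pytest.raises(ValueError, match="universe"):
            score_pairs(edges, regulons20, frozenset())


class TestSelectPairs:
    def test_fewer_pairs_than_limits(self):
        pairs = pd.DataFrame({"p": np.linspace(0.01, 0.05, 5)})
        tier, triad = select_pairs(pairs)
        assert len(tier) == 5 and len(triad) == 5

    def test_limits_match_independent_sort(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=150)
        pairs = pd.DataFrame(
            {
                "lncrna_id": [f"L{i:03d}" for i in range(150)],
                "tf_id": "TF1",
                "p": np.sort(p),
                "fold_enrichment": 2.0,
            }
        )
        tier, triad = select_pairs(pairs)
        assert len(tier) == 100 and len(triad) == 10
        assert tier["p"].tolist() == sorted(p)[:100]
        assert triad["p"].tolist() == sorted(p)[:10]

    def test_tie_break_is_lexicographic_and_stable(self, regulons20):
        edges = _edges(
            [("L2", f"g{i}", 0.8, 0.01) for i in range(5)]
            + [("L1", f"g{i}", 0.8, 0.01) for i in range(5)]
        )
        p1 = score_pairs(edges, regulons20, regulons20.universe)
        p2 = score_pairs(edges, regulons20, regulons20.universe)
        assert p1.equals(p2)
        tied = p1[p1["tf_id"] == "TF1"]
        assert tied["lncrna_id"].tolist() == sorted(tied["lncrna_id"])


class TestBuildTriads:
    def test_planted_triads_recovered_with_all_targets(self, clean_dataset):
        _, (mrna, lnc, regulons, truth) = clean_dataset
        edges = coexpression_pairs(lnc, mrna)
        pairs = score_pairs(edges, regulons, frozenset(mrna.gene_ids))
        _, triad_tier = select_pairs(pairs)
        triads = build_triads(triad_tier, edges, regulons)
        by_pair = {(t.lncrna_id, t.tf_id): t for t in triads}
        for lnc_id, tf, targets in truth.planted_triads:
            assert (lnc_id, tf) in by_pair
            assert by_pair[(lnc_id, tf)].target_ids == targets

    def test_targets_subset_of_overlap(self, regulons20):
        edges = _edges([("L1", f"g{i}", 0.8, 0.01) for i in (0, 1, 2, 11)])
        pairs = score_pairs(edges, regulons20, regulons20.universe)
        _, tier = select_pairs(pairs)
        for t in build_triads(tier, edges, regulons20):
            k = pairs.set_index(["lncrna_id", "tf_id"]).loc[(t.lncrna_id, t.tf_id), "k"]
            assert len(t.target_ids) <= k

    def test_de_filter_can_drop_triad(self, regulons20, caplog):
        edges = _edges([("L1", f"g{i}", 0.8, 0.01) for i in (0, 1, 2)])
        pairs = score_pairs(edges, regulons20, regulons20.universe)
        _, tier = select_pairs(pairs)
        with caplog.at_level("INFO", logger="lnctrans"):
            triads = build_triads(tier, edges, regulons20, de_mrnas=frozenset({"g19"}))
        assert triads == []
        assert "dropped" in caplog.text

    def test_unknown_regulon_raises(self, regulons20):
        tier = pd.DataFrame(
            [{"lncrna_id": "L1", "tf_id": "TFX", "k": 1, "n": 1, "K": 5,
              "N": 20, "p": 0.1, "fold_enrichment": 1.0}]
        )
        with pytest.raises(ValueError, match="TFX"):
            build_triads(tier, _edges([("L1", "g0", 0.8, 0.01)]), regulons20)


class TestAssembleNetwork:
    def test_one_triad_three_targets_gives_seven_edges(self):
        t = TransTriad(
            "L1", "TF1", frozenset({"g1", "g2", "g3"}), 0.001,
            {g: (0.9, 0.01) for g in ("g1", "g2", "g3")},
        )
        nodes, edges = assemble_network([t])
        assert len(nodes) == 5
        assert len(edges) == 7  # 1 lncRNA-TF + 3 lncRNA-target + 3 TF-target

    def test_shared_tf_emitted_once(self):
        ts = [
            TransTriad("L1", "TF1", frozenset({"g1"}), 0.001, {"g1": (0.9, 0.01)}),
            TransTriad("L2", "TF1", frozenset({"g2"}), 0.002, {"g2": (0.8, 0.02)}),
        ]
        nodes, _ = assemble_network(ts)
        assert [n for n, t in nodes if t == "TF"] == ["TF1"]

    def test_gene_both_tf_and_target_keeps_tf_type(self):
        ts = [
            TransTriad("L1", "TF1", frozenset({"TF2"}), 0.001, {"TF2": (0.9, 0.01)}),
            TransTriad("L1", "TF2", frozenset({"g1"}), 0.002, {"g1": (0.8, 0.02)}),
        ]
        nodes, _ = assemble_network(ts)
        assert dict(nodes)["TF2"] == "TF"

    def test_empty_triads_empty_network(self):
        assert assemble_network([]) == ([], [])

    def test_audit_accepts_consistent_network(self, regulons20):
        edges = _edges([("L1", f"g{i}", 0.8, 0.01) for i in (0, 1, 2)])
        pairs = score_pairs(edges, regulons20, regulons20.universe)
        _, tier = select_pairs(pairs)
        triads = build_triads(tier, edges, regulons20)
        nodes, net_edges = assemble_network(triads)
        audit_network(nodes, net_edges, edges, regulons20)

    def test_audit_rejects_untraceable_edge(self, regulons20):
        edges = _edges([("L1", "g0", 0.8, 0.01)])
        nodes = [("L1", "lncRNA"), ("g5", "target")]
        bad = [("L1", "coexpression", "g5", 0.9)]
        with pytest.raises(ValueError, match="supporting"):
            audit_network(nodes, bad, edges, regulons20)
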