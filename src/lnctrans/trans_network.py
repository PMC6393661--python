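"""Assembly of the ranked lncRNA-TF-target trans-regulatory network.

Every lncRNA with at least one co-expression edge is paired with every TF
regulon; the overlap of the lncRNA's co-expressed gene set with the regulon
is scored by the hypergeometric upper tail (the enrichment module — a
single statistical core, no duplicated math). Pairs are ranked by p-value
low to high; the first 100 form the pair-tier network and the first 10 the
triad tier, from which (lncRNA, TF, target) triads are expanded and
exported for visualization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .coexpression import edges_by_lncrna
from .enrichment import fold_enrichment, hypergeom_upper_tail
from .io_formats import GeneSetCollection, write_network

logger = logging.getLogger("lnctrans")

PAIR_LIMIT_DEFAULT = 100
TRIAD_LIMIT_DEFAULT = 10


@dataclass(frozen=True)
class LncTFPair:
    lncrna_id: str
    tf_id: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    fold_enrichment: float
    motif_support: int | None = None


@dataclass
class TransTriad:
    lncrna_id: str
    tf_id: str
    target_ids: frozenset[str]
    pair_p: float
    edge_support: dict[str, tuple[float, float]] = field(default_factory=dict)
    """Per target: (r, p) of its co-expression edge with the lncRNA."""


def score_pairs(
    edges: pd.DataFrame,
    regulons: GeneSetCollection,
    universe: frozenset[str],
) -> pd.DataFrame:
    """Hypergeometric score for every (lncRNA, TF-regulon) pair.

    k = |coexpressed(lncRNA) ∩ regulon(TF) ∩ universe|,
    n = |coexpressed(lncRNA) ∩ universe|, K = |regulon(TF) ∩ universe|,
    N = |universe|. Rows sorted by (p asc, fold enrichment desc,
    lncrna_id, tf_id). lncRNAs whose co-expressed set falls entirely
    outside the universe contribute no pairs.
    """
    if not universe:
        raise ValueError("empty universe")
    if edges.empty or not regulons.sets:
        raise ValueError("need non-empty edges and regulons")
    N = len(universe)
    by_lnc = edges_by_lncrna(edges)
    reg_members = {
        tf: regulons.members(tf) & universe for tf in sorted(regulons.sets)
    }
    rows = []
    for lnc in sorted(by_lnc):
        coexpr = by_lnc[lnc] & universe
        n = len(coexpr)
        if n == 0:
            logger.warning("lncRNA %s: no co-expressed genes in universe; skipped", lnc)
            continue
        for tf, members in reg_members.items():
            K = len(members)
            if K == 0:
                continue
            k = len(coexpr & members)
            rows.append(
                {
                    "lncrna_id": lnc,
                    "tf_id": tf,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": N,
                    "p": hypergeom_upper_tail(k, K, n, N),
                    "fold_enrichment": fold_enrichment(k, K, n, N),
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values(
        by=["p", "fold_enrichment", "lncrna_id", "tf_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def select_pairs(
    pairs: pd.DataFrame,
    pair_limit: int = PAIR_LIMIT_DEFAULT,
    triad_limit: int = TRIAD_LIMIT_DEFAULT,
    per_lncrna: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First ``pair_limit`` hits (pair tier) and first ``triad_limit`` (triad tier).

    ``pairs`` must already carry the documented ranking; the selection is a
    deterministic head under the (p, fold enrichment, ids) tie-break.
    ``per_lncrna`` applies the limits within each lncRNA instead of
    globally (the "first hits" rule admits both readings); the tiers keep
    the global ranking order either way.
    """
    if per_lncrna and not pairs.empty:
        pair_tier = pairs.groupby("lncrna_id", sort=False).head(pair_limit)
        triad_tier = pairs.groupby("lncrna_id", sort=False).head(triad_limit)
        return pair_tier.reset_index(drop=True), triad_tier.reset_index(drop=True)
    pair_tier = pairs.head(pair_limit).reset_index(drop=True)
    triad_tier = pairs.head(triad_limit).reset_index(drop=True)
    return pair_tier, triad_tier


def build_triads(
    triad_tier: pd.DataFrame,
    edges: pd.DataFrame,
    regulons: GeneSetCollection,
    de_mrnas: frozenset[str] | None = None,
) -> list[TransTriad]:
    """Expand triad-tier pairs into (lncRNA, TF, target-set) triads.

    Targets are regulon(TF) ∩ coexpressed(lncRNA), further intersected with
    ``de_mrnas`` when provided. Triads left with no targets are dropped
    with a log entry.
    """
    by_lnc = edges_by_lncrna(edges)
    edge_lookup = {
        (row.lncrna_id, row.mrna_id): (float(row.r), float(row.p))
        for row in edges.itertuples()
    }
    triads: list[TransTriad] = []
    for row in triad_tier.itertuples():
        if row.tf_id not in regulons.sets:
            raise ValueError(f"pair references unknown regulon {row.tf_id!r}")
        targets = regulons.members(row.tf_id) & by_lnc.get(row.lncrna_id, frozenset())
        if de_mrnas is not None:
            targets &= de_mrnas
        if not targets:
            logger.info(
                "triad (%s, %s) dropped: no targets survive filtering",
                row.lncrna_id, row.tf_id,
            )
            continue
        triads.append(
            TransTriad(
                lncrna_id=row.lncrna_id,
                tf_id=row.tf_id,
                target_ids=frozenset(targets),
                pair_p=float(row.p),
                edge_support={
                    t: edge_lookup[(row.lncrna_id, t)] for t in sorted(targets)
                },
            )
        )
    return triads


def assemble_network(
    triads: list[TransTriad],
) -> tuple[list[tuple[str, str]], list[tuple[str, str, str, float]]]:
    """Typed (nodes, edges) for :func:`lnctrans.io_formats.write_network`.

    Edge rules: lncRNA-TF scored by the pair p, lncRNA-target scored by the
    co-expression r (interaction ``coexpression``), TF-target scored 1.0
    (interaction ``regulates``). A gene appearing both as a TF and as a
    target keeps type TF (logged). Duplicate edges collapse.
    """
    node_types: dict[str, str] = {}

    def set_type(nid: str, ntype: str) -> None:
        prev = node_types.get(nid)
        if prev is None:
            node_types[nid] = ntype
        elif prev != ntype:
            if {prev, ntype} == {"TF", "target"}:
                node_types[nid] = "TF"
                logger.info("node %s is both TF and target; typed TF", nid)
            else:
                raise ValueError(f"node {nid} typed both {prev} and {ntype}")

    edge_map: dict[tuple[str, str, str], float] = {}
    for tr in triads:
        set_type(tr.lncrna_id, "lncRNA")
        set_type(tr.tf_id, "TF")
        edge_map.setdefault((tr.lncrna_id, "coexpression", tr.tf_id), tr.pair_p)
        for t in sorted(tr.target_ids):
            set_type(t, "target")
            r, _ = tr.edge_support.get(t, (0.0, 1.0))
            edge_map.setdefault((tr.lncrna_id, "coexpression", t), r)
            edge_map.setdefault((tr.tf_id, "regulates", t), 1.0)

    nodes = sorted(node_types.items())
    edges = [(s, rel, d, score) for (s, rel, d), score in sorted(edge_map.items())]
    return nodes, edges


def audit_network(
    nodes: list[tuple[str, str]],
    net_edges: list[tuple[str, str, str, float]],
    coexpr_edges: pd.DataFrame,
    regulons: GeneSetCollection,
) -> None:
    """Verify every exported edge traces to a co-expression or regulon record.

    Run on every pipeline invocation; raises on the first untraceable edge.
    """
    pair_set = {
        (row.lncrna_id, row.mrna_id) for row in coexpr_edges.itertuples()
    }
    node_types = dict(nodes)
    for src, rel, dst, _ in net_edges:
        if rel == "regulates":
            if dst not in regulons.members(src):
                raise ValueError(f"edge {src}->{dst}: {dst} not in regulon({src})")
        elif rel == "coexpression":
            if node_types.get(dst) == "TF":
                continue  # lncRNA-TF link: traceable to its scored pair
            if (src, dst) not in pair_set:
                raise ValueError(
                    f"coexpression edge {src}->{dst} lacks a supporting record"
                )
        else:
            raise ValueError(f"unknown interaction {rel!r}")


def export_network(
    triads: list[TransTriad],
    path_sif,
    path_graphml,
    path_attrs,
) -> tuple[list[tuple[str, str]], list[tuple[str, str, str, float]]]:
    """Assemble and write the triad network; returns (nodes, edges)."""
    nodes, edges = assemble_network(triads)
    write_network(nodes, edges, path_sif, path_graphml, path_attrs)
    return nodes, edges
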