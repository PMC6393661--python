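"""Hypergeometric over-representation analysis.

The shared statistical core of the pipeline: a query gene set is tested
against each reference set (GO/KEGG term or TF regulon) in a collection.
With a universe of N genes of which K belong to the reference set, and a
query of n genes overlapping the reference in k, the p-value is the upper
tail P(X >= k) for X ~ Hypergeometric(N, K, n), and fold enrichment is
(k/n)/(K/N). A term is significant under the pipeline's default rule when
raw p < 0.05 and fold enrichment > 2; BH q-values are reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

logger = logging.getLogger("lnctrans")

P_THRESHOLD_DEFAULT = 0.05
FE_THRESHOLD_DEFAULT = 2.0


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    q_value: float
    fold_enrichment: float
    significant: bool


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the reference-set size, n the number of
    draws (query size); k = 0 returns exactly 1.
    """
    if not (0 <= k <= min(n, K) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(
            f"inconsistent counts k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fold_enrichment(k: int, K: int, n: int, N: int) -> float:
    """(k/n) / (K/N); 0 when k = 0."""
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError("n, K and N must be positive")
    if k == 0:
        return 0.0
    return (k / n) / (K / N)


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    fe_threshold: float = FE_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Over-representation of ``query`` in every set of ``collection``.

    The query is first intersected with the collection's universe (an empty
    harmonized query is an error). One row per reference set with nonzero
    possible overlap; BH q computed across the whole collection; sorted by
    (p asc, fold_enrichment desc, set_id). Significance uses raw p and
    fold enrichment.
    """
    universe = collection.universe
    q = frozenset(query) & universe
    if not q:
        raise ValueError("query is empty after intersection with the universe")
    N = len(universe)
    n = len(q)
    rows = []
    for sid in sorted(collection.sets):
        members = collection.members(sid) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(q & members)
        rows.append(
            {
                "set_id": sid,
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
        return df.assign(q=[], significant=[])
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = (df["p"] < p_threshold) & (df["fold_enrichment"] > fe_threshold)
    df = df.sort_values(
        by=["p", "fold_enrichment", "set_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df[["set_id", "k", "n", "K", "N", "p", "q", "fold_enrichment", "significant"]]


def annotate_lncrna(
    lncrna_id: str,
    edges: pd.DataFrame,
    collection: GeneSetCollection,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    fe_threshold: float = FE_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Predict an lncRNA's functions from its co-expressed mRNA set.

    The enriched reference terms of the genes co-expressed with the lncRNA
    are taken as its predicted functional terms. An lncRNA with no edges
    yields an empty annotation (logged), not an error.
    """
    coexpressed = frozenset(edges.loc[edges["lncrna_id"] == lncrna_id, "mrna_id"])
    if not coexpressed:
        logger.warning("lncRNA %s has no co-expressed mRNAs; empty annotation", lncrna_id)
        return pd.DataFrame(
            columns=["set_id", "k", "n", "K", "N", "p", "q", "fold_enrichment", "significant"]
        )
    return enrich(coexpressed, collection, p_threshold, fe_threshold)
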