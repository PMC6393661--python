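"""All-pairs lncRNA-mRNA Pearson co-expression with exact t-based significance.

An lncRNA and an mRNA are co-expressed when |r| > 0.7 and the two-sided
p-value of r is below 0.05. The p-value uses the exact transform
t = r*sqrt(n-2)/sqrt(1-r^2) against Student's t with n-2 degrees of
freedom — at n=6 this has the closed form p = 1 - 1.5|r| + 0.5|r|^3, which
serves as an independent oracle in tests. Correlations are computed on
log2(FPKM+1) by default, consistent with the differential-expression
module; raw-FPKM mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

logger = logging.getLogger("lnctrans")

R_THRESHOLD_DEFAULT = 0.7
P_THRESHOLD_DEFAULT = 0.05


@dataclass(frozen=True)
class CoexprEdge:
    lncrna_id: str
    mrna_id: str
    r: float
    p_value: float
    n: int


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("zero-variance vector")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def correlation_p(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the exact t transform.

    t = r*sqrt(n-2)/sqrt(1-r^2), df = n-2. By convention p(0, n) = 1 and
    p(+-1, n) = 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    r = float(r)
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _correlation_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row correlation of two (genes x samples) arrays."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.sqrt((ac * ac).sum(axis=1))
    bn = np.sqrt((bc * bc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac @ bc.T) / np.outer(an, bn)
    return np.clip(r, -1.0, 1.0)


def coexpression_pairs(
    lnc: ExpressionMatrix,
    mrna: ExpressionMatrix,
    r_threshold: float = R_THRESHOLD_DEFAULT,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Evaluate every lncRNA x mRNA pair; retain |r| > r_threshold, p < p_threshold.

    Zero-variance genes are excluded from edges with a logged reason rather
    than raising. Returns a DataFrame with columns lncrna_id, mrna_id, r, p,
    n sorted by (p asc, |r| desc, lncrna_id, mrna_id).
    """
    if lnc.sample_ids != mrna.sample_ids:
        raise ValueError("sample sets/order differ between lncRNA and mRNA matrices")
    n = len(lnc.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")

    a = lnc.values.to_numpy(dtype=float)
    b = mrna.values.to_numpy(dtype=float)
    if log_transform:
        a = np.log2(a + pseudocount)
        b = np.log2(b + pseudocount)

    const_a = a.var(axis=1) == 0
    const_b = b.var(axis=1) == 0
    for gid in np.asarray(lnc.gene_ids)[const_a]:
        logger.warning("lncRNA %s has zero variance; excluded from co-expression", gid)
    for gid in np.asarray(mrna.gene_ids)[const_b]:
        logger.warning("mRNA %s has zero variance; excluded from co-expression", gid)

    r = _correlation_matrix(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)

    keep = (np.abs(r) > r_threshold) & (p < p_threshold)
    keep &= ~const_a[:, None] & ~const_b[None, :]
    li, mi = keep.nonzero()

    lnc_ids = np.asarray(lnc.gene_ids)
    mrna_ids = np.asarray(mrna.gene_ids)
    out = pd.DataFrame(
        {
            "lncrna_id": lnc_ids[li],
            "mrna_id": mrna_ids[mi],
            "r": r[li, mi],
            "p": p[li, mi],
            "n": n,
        }
    )
    out = out.sort_values(
        by=["p", "r", "lncrna_id", "mrna_id"],
        key=lambda col: -col.abs() if col.name == "r" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def edges_by_lncrna(edges: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Co-expressed mRNA set per lncRNA from an edge table."""
    return {
        lnc: frozenset(sub["mrna_id"])
        for lnc, sub in edges.groupby("lncrna_id", sort=True)
    }
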