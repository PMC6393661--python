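"""Differential expression of mRNAs and lncRNAs from FPKM.

Selection rule: a gene is called differentially expressed when its raw
two-sided p-value is below ``p_threshold`` (default 0.05) and |log2FC|
exceeds ``fc_threshold`` (default 1). The test statistic is Welch's
two-sample t on log2(FPKM + pseudocount) — a transparent, oracle-checkable
choice for a threshold-based selection rule on normalized expression.
BH-adjusted q-values are reported alongside but never used for selection;
a ``signed_fc`` mode restricts calls to up-regulation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

P_THRESHOLD_DEFAULT = 0.05
FC_THRESHOLD_DEFAULT = 1.0
PSEUDOCOUNT_DEFAULT = 1.0


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    mean_case: float
    mean_control: float
    log2fc: float
    p_value: float
    q_value: float
    is_de: bool


def log2_fold_change(
    mean_case: float, mean_control: float, pseudocount: float = PSEUDOCOUNT_DEFAULT
) -> float:
    """log2((mean_case + pseudocount) / (mean_control + pseudocount)).

    The pseudocount (FPKM units) keeps unexpressed genes finite; with both
    means zero the fold change is exactly 0.
    """
    if mean_case < 0 or mean_control < 0:
        raise ValueError("FPKM means must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return float(np.log2((mean_case + pseudocount) / (mean_control + pseudocount)))


def de_test(
    matrix: ExpressionMatrix,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
    pseudocount: float = PSEUDOCOUNT_DEFAULT,
    signed_fc: bool = False,
) -> pd.DataFrame:
    """Welch t-test per gene on log2(FPKM + pseudocount), case vs control.

    Returns a DataFrame (gene order preserved) with columns gene_id,
    mean_case, mean_control, log2fc, p, q, is_de. Genes with zero variance
    in both groups get p=1 when the group means are equal, p=0 otherwise.
    """
    case = matrix.samples_in_group("case")
    ctrl = matrix.samples_in_group("control")
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(case)} case / {len(ctrl)} control"
        )
    x = np.log2(matrix.values[case].to_numpy() + pseudocount)
    y = np.log2(matrix.values[ctrl].to_numpy() + pseudocount)

    mean_case = matrix.values[case].mean(axis=1).to_numpy()
    mean_ctrl = matrix.values[ctrl].mean(axis=1).to_numpy()
    l2fc = np.log2((mean_case + pseudocount) / (mean_ctrl + pseudocount))

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    # degenerate genes: zero variance in both groups
    degenerate = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    equal_means = np.isclose(x.mean(axis=1), y.mean(axis=1))
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    p = np.nan_to_num(p, nan=1.0)

    q = multipletests(p, method="fdr_bh")[1]
    passes_fc = l2fc > fc_threshold if signed_fc else np.abs(l2fc) > fc_threshold
    is_de = (p < p_threshold) & passes_fc

    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "log2fc": l2fc,
            "p": p,
            "q": q,
            "is_de": is_de,
        }
    )


def de_gene_set(de_table: pd.DataFrame) -> frozenset[str]:
    """The set of gene ids flagged differentially expressed."""
    return frozenset(de_table.loc[de_table["is_de"], "gene_id"])
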