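"""Relative expression from qPCR cycle thresholds by the 2^-ddCt method.

dCt = Ct(target) - Ct(reference gene) per sample; ddCt subtracts the mean
control dCt (the calibrator); relative expression is 2^-ddCt with
amplification efficiency fixed at 2. Case-vs-control significance is a
two-sided Student t-test on the per-sample dCt values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample_id", "group", "gene_id", "ct_target", "ct_reference"]


@dataclass(frozen=True)
class DdctResult:
    gene_id: str
    relative_expression: dict[str, float]  # per case sample, 2^-ddCt
    mean_case: float
    mean_control: float  # == 1 when the control mean is the calibrator definitionally on average
    p_value: float


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def ddct(
    records: pd.DataFrame,
    gene_id: str,
    per_pair: bool = False,
) -> DdctResult:
    """2^-ddCt relative expression for one gene plus a group t-test.

    ``records`` needs columns sample_id, group, gene_id, ct_target,
    ct_reference with >=1 case and >=1 control row for the gene. The
    calibrator is the control-group mean dCt; ``per_pair`` instead
    calibrates each case sample against the control sample of the same
    index (requires equal group sizes).
    """
    sub = records.loc[records["gene_id"] == gene_id]
    if sub.empty:
        raise ValueError(f"no records for gene {gene_id!r}")
    ct = sub[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValueError(f"Ct values for {gene_id!r} must be finite and > 0")
    dct = sub["ct_target"].to_numpy(float) - sub["ct_reference"].to_numpy(float)
    is_case = (sub["group"] == "case").to_numpy()
    is_ctrl = (sub["group"] == "control").to_numpy()
    if not is_case.any() or not is_ctrl.any():
        raise ValueError(f"gene {gene_id!r}: need both case and control records")

    case_ids = sub.loc[is_case, "sample_id"].tolist()
    dct_case = dct[is_case]
    dct_ctrl = dct[is_ctrl]

    if per_pair:
        if len(dct_case) != len(dct_ctrl):
            raise ValueError("per_pair calibration needs equal group sizes")
        ddct_case = dct_case - dct_ctrl
    else:
        ddct_case = dct_case - dct_ctrl.mean()
    rel = 2.0 ** (-ddct_case)

    if len(dct_case) >= 2 and len(dct_ctrl) >= 2:
        _, p = stats.ttest_ind(dct_case, dct_ctrl, equal_var=True)
        p = float(p) if np.isfinite(p) else 1.0
    else:
        p = float("nan")

    rel_ctrl = 2.0 ** (-(dct_ctrl - dct_ctrl.mean()))
    return DdctResult(
        gene_id=gene_id,
        relative_expression=dict(zip(case_ids, map(float, rel))),
        mean_case=float(rel.mean()),
        mean_control=float(rel_ctrl.mean()),
        p_value=p,
    )


def ddct_table(records: pd.DataFrame, per_pair: bool = False) -> pd.DataFrame:
    """Run :func:`ddct` for every gene in a Ct table; tidy summary."""
    rows = []
    for gene in sorted(records["gene_id"].unique()):
        res = ddct(records, gene, per_pair=per_pair)
        rows.append(
            {
                "gene_id": gene,
                "mean_relative_expression": res.mean_case,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)
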