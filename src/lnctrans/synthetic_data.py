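"""Synthetic case/control expression data with planted trans-regulatory structure.

The generator emulates the study design the pipeline targets: a small
case-vs-control FPKM experiment (default 3 + 3 samples, as in an E14.5
embryonic palate comparison) in which some lncRNAs act in trans through a
transcription factor on that factor's regulon.

Generative model (log2 scale)
-----------------------------
For each TF ``t`` a latent per-sample activity

    a_{t,s} ~ Normal(delta * 1[s in case], 1),

with ``delta = de_log2fc`` for TFs belonging to planted triads and 0
otherwise. Expression of a regulon target gene ``g`` of TF ``t``:

    log2 x_{g,s} = baseline_log2fpkm + activity_weight * a_{t,s} + eps,
    eps ~ Normal(0, noise_sd).

The TF's own transcript and each planted triad's lncRNA load on the same
activity with the same weight, which is what makes the lncRNA-TF pair and
the lncRNA-target co-expression a recoverable planted signal. Background
genes are baseline plus noise. FPKM = 2**(log2 value), clipped at zero
(clipping cannot trigger since 2**x > 0; the clip guards the contract).

Identical seed => byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    write_expression_matrix,
    write_gmt,
)

logger = logging.getLogger("lnctrans")

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults mirror a 3-vs-3 case/control design; parameter-recovery tests
    use more samples because Pearson r at n=6 is highly variable.
    """

    n_case: int = 3
    n_control: int = 3
    n_mrna: int = 500
    n_lncrna: int = 50
    n_tf: int = 10
    regulon_size: int = 20
    n_planted_triads: int = 5
    de_log2fc: float = 1.5
    activity_weight: float = 1.0
    noise_sd: float = 0.3
    baseline_log2fpkm: float = 5.0
    seed: int = 0
    lncrna_length: int = 500

    def __post_init__(self) -> None:
        counts = {
            "n_case": self.n_case,
            "n_control": self.n_control,
            "n_mrna": self.n_mrna,
            "n_lncrna": self.n_lncrna,
            "n_tf": self.n_tf,
            "regulon_size": self.regulon_size,
            "n_planted_triads": self.n_planted_triads,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_planted_triads > min(self.n_tf, self.n_lncrna):
            raise ValueError(
                "n_planted_triads must not exceed min(n_tf, n_lncrna)"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        need = self.n_tf * (1 + self.regulon_size)
        if self.n_mrna < need:
            raise ValueError(
                f"n_mrna={self.n_mrna} too small: need >= n_tf*(1+regulon_size)={need}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`generate_dataset`.

    ``de_genes`` maps every gene carrying a case/control mean shift to its
    sign (+1 up in case, -1 down); ``planted_triads`` lists
    (lncRNA, TF, regulon target set); ``latent_activities`` is the TF x
    sample matrix of activities the expression was generated from.
    """

    de_genes: dict[str, int]
    regulons: dict[str, frozenset[str]]
    planted_triads: list[tuple[str, str, frozenset[str]]]
    latent_activities: pd.DataFrame
    motifs: dict[str, str] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)


def _gene_names(config: SimConfig) -> tuple[list[str], dict[str, list[str]], list[str]]:
    tfs = [f"TF{i + 1:02d}" for i in range(config.n_tf)]
    targets: dict[str, list[str]] = {}
    k = 0
    for tf in tfs:
        targets[tf] = [f"G{k + j + 1:04d}" for j in range(config.regulon_size)]
        k += config.regulon_size
    n_bg = config.n_mrna - config.n_tf - k
    background = [f"G{k + j + 1:04d}" for j in range(n_bg)]
    return tfs, targets, background


def generate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GeneSetCollection, SyntheticTruth]:
    """Generate (mRNA matrix, lncRNA matrix, regulon collection, truth)."""
    rng = np.random.default_rng(config.seed)
    samples = [f"case{i + 1}" for i in range(config.n_case)] + [
        f"ctrl{i + 1}" for i in range(config.n_control)
    ]
    groups = {s: ("case" if s.startswith("case") else "control") for s in samples}
    n_s = len(samples)
    is_case = np.array([groups[s] == "case" for s in samples], dtype=float)

    tfs, tf_targets, background = _gene_names(config)
    lncrnas = [f"LNC{i + 1:03d}" for i in range(config.n_lncrna)]
    planted_tfs = tfs[: config.n_planted_triads]
    planted_lncs = lncrnas[: config.n_planted_triads]

    # latent TF activities; planted-triad TFs carry the case-shift delta
    delta = np.array(
        [config.de_log2fc if t in planted_tfs else 0.0 for t in tfs]
    )
    activities = rng.standard_normal((config.n_tf, n_s)) + delta[:, None] * is_case

    w = config.activity_weight
    b = config.baseline_log2fpkm
    sd = config.noise_sd

    mrna_rows: dict[str, np.ndarray] = {}
    for i, tf in enumerate(tfs):
        mrna_rows[tf] = b + w * activities[i] + rng.normal(0.0, sd, n_s)
        for g in tf_targets[tf]:
            mrna_rows[g] = b + w * activities[i] + rng.normal(0.0, sd, n_s)
    for g in background:
        mrna_rows[g] = b + rng.normal(0.0, sd, n_s)

    lnc_rows: dict[str, np.ndarray] = {}
    for j, lnc in enumerate(lncrnas):
        if j < config.n_planted_triads:
            lnc_rows[lnc] = b + w * activities[j] + rng.normal(0.0, sd, n_s)
        else:
            lnc_rows[lnc] = b + rng.normal(0.0, sd, n_s)

    mrna_order = tfs + [g for tf in tfs for g in tf_targets[tf]] + background
    mrna_log2 = np.vstack([mrna_rows[g] for g in mrna_order])
    lnc_log2 = np.vstack([lnc_rows[g] for g in lncrnas])

    mrna_fpkm = np.clip(np.exp2(mrna_log2), 0.0, None)
    lnc_fpkm = np.clip(np.exp2(lnc_log2), 0.0, None)

    mrna = ExpressionMatrix(
        values=pd.DataFrame(mrna_fpkm, index=mrna_order, columns=samples),
        groups=groups,
        biotype={g: "mRNA" for g in mrna_order},
    )
    lnc = ExpressionMatrix(
        values=pd.DataFrame(lnc_fpkm, index=lncrnas, columns=samples),
        groups=groups,
        biotype={g: "lncRNA" for g in lncrnas},
    )

    regulons = GeneSetCollection(
        sets={
            tf: (f"targets of {tf}", frozenset(tf_targets[tf])) for tf in tfs
        },
        universe=frozenset(mrna_order),
    )

    # genes carrying a case shift: the planted TFs, their targets, their lncRNAs
    sign = 1 if config.de_log2fc >= 0 else -1
    de_genes: dict[str, int] = {}
    if config.de_log2fc != 0:
        for tf in planted_tfs:
            de_genes[tf] = sign
            for g in tf_targets[tf]:
                de_genes[g] = sign
        for lnc_id in planted_lncs:
            de_genes[lnc_id] = sign

    # motifs and lncRNA sequences: one 8-mer consensus per TF, embedded in
    # its planted partner lncRNA so the binding scan has a recoverable hit
    motifs = {
        tf: "".join(rng.choice(NUCLEOTIDES, size=8)) for tf in tfs
    }
    sequences: dict[str, str] = {}
    for j, lnc_id in enumerate(lncrnas):
        seq = rng.choice(NUCLEOTIDES, size=config.lncrna_length)
        if j < config.n_planted_triads:
            pos = int(rng.integers(0, config.lncrna_length - 8))
            seq[pos : pos + 8] = list(motifs[tfs[j]])
        sequences[lnc_id] = "".join(seq)

    truth = SyntheticTruth(
        de_genes=de_genes,
        regulons={tf: frozenset(tf_targets[tf]) for tf in tfs},
        planted_triads=[
            (planted_lncs[i], planted_tfs[i], frozenset(tf_targets[planted_tfs[i]]))
            for i in range(config.n_planted_triads)
        ],
        latent_activities=pd.DataFrame(activities, index=tfs, columns=samples),
        motifs=motifs,
        sequences=sequences,
    )
    return mrna, lnc, regulons, truth


# ---------------------------------------------------------------------------
# qPCR table synthesis (inverse of the 2^-ddCt computation)
# ---------------------------------------------------------------------------

def generate_qpcr_table(
    fold_changes: dict[str, float],
    ct_reference: float = 15.0,
    n_case: int = 3,
    n_control: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    base_dct: float = 4.0,
) -> pd.DataFrame:
    """Construct a Ct table whose 2^-ddCt analysis recovers ``fold_changes``.

    For each gene with target fold change ``f`` (case relative to control),
    control samples get dCt = ``base_dct`` and case samples get
    dCt = base_dct - log2(f), so ddCt = -log2(f) and 2^-ddCt = f exactly at
    zero noise. Gaussian Ct noise (``noise_sd``, cycles) is added to the
    target Ct when requested.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict[str, object]] = []
    for gene in sorted(fold_changes):
        f = fold_changes[gene]
        if not (f > 0):
            raise ValueError(f"fold change for {gene!r} must be > 0, got {f}")
        case_dct = base_dct - np.log2(f)
        for i in range(n_case):
            ct_t = ct_reference + case_dct + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
            rows.append(
                dict(sample_id=f"case{i + 1}", group="case", gene_id=gene,
                     ct_target=float(ct_t), ct_reference=float(ct_reference))
            )
        for i in range(n_control):
            ct_t = ct_reference + base_dct + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
            rows.append(
                dict(sample_id=f"ctrl{i + 1}", group="control", gene_id=gene,
                     ct_target=float(ct_t), ct_reference=float(ct_reference))
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk emission (the formats io_formats reads)
# ---------------------------------------------------------------------------

def write_dataset(
    config: SimConfig,
    outdir: str | Path,
) -> SyntheticTruth:
    """Generate a dataset and write every file the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mrna, lnc, regulons, truth = generate_dataset(config)
    write_expression_matrix(
        mrna, outdir / "mrna_fpkm.tsv", outdir / "groups.tsv",
        outdir / "mrna_biotype.tsv",
    )
    write_expression_matrix(lnc, outdir / "lncrna_fpkm.tsv",
                            biotype_path=outdir / "lncrna_biotype.tsv")
    write_gmt(regulons, outdir / "regulons.gmt")
    with open(outdir / "lncrna.fasta", "w", encoding="utf-8") as fh:
        for lnc_id in sorted(truth.sequences):
            fh.write(f">{lnc_id}\n{truth.sequences[lnc_id]}\n")
    with open(outdir / "motifs.tsv", "w", encoding="utf-8") as fh:
        fh.write("tf_id\tmotif\n")
        for tf in sorted(truth.motifs):
            fh.write(f"{tf}\t{truth.motifs[tf]}\n")
    logger.info(
        "synthetic dataset written to %s (%d mRNAs, %d lncRNAs, %d TFs)",
        outdir, config.n_mrna, config.n_lncrna, config.n_tf,
    )
    return truth


RECOVERY_CONFIG = SimConfig(
    n_case=10,
    n_control=10,
    n_mrna=500,
    n_lncrna=50,
    n_tf=10,
    regulon_size=20,
    n_planted_triads=5,
    de_log2fc=1.5,
    activity_weight=1.0,
    noise_sd=0.3,
)
"""Configuration used by the parameter-recovery tests (larger n for stable r)."""


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """Global-null configuration: no activity coupling, no DE shift."""
    cfg = replace(RECOVERY_CONFIG, activity_weight=0.0, de_log2fc=0.0, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg
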