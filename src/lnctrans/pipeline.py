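"""End-to-end orchestration: simulate/load -> DE -> co-expression -> pair
scoring -> triad assembly -> network export, with a run manifest.

All thresholds default to the frozen paper-mode constants below; a rerun
with the same config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coexpression import coexpression_pairs
from .diffexpr import de_gene_set, de_test
from .enrichment import annotate_lncrna
from .io_formats import (
    GeneSetCollection,
    read_expression_matrix,
    read_gmt,
)
from .motif_scan import annotate_pairs, read_fasta, read_motif_table, scan_all
from .synthetic_data import SimConfig, generate_dataset
from .trans_network import (
    audit_network,
    build_triads,
    export_network,
    score_pairs,
    select_pairs,
)

logger = logging.getLogger("lnctrans")

# Frozen paper-mode defaults: significance p < 0.05, fold enrichment > 2,
# |log2FC| > 1, co-expression |r| > 0.7, first-100 pair and first-10 triad
# selection. Asserted by a dedicated test; do not edit casually.
PAPER_MODE = {
    "p_de": 0.05,
    "fc": 1.0,
    "r": 0.7,
    "p_coexpr": 0.05,
    "p_enrich": 0.05,
    "fe": 2.0,
    "pair_limit": 100,
    "triad_limit": 10,
}


@dataclass
class PipelineConfig:
    """Thresholds, mode flags and file paths for one pipeline run."""

    # inputs: either explicit matrices or a simulation
    mrna_path: str | None = None
    lncrna_path: str | None = None
    groups_path: str | None = None
    mrna_biotype_path: str | None = None
    lncrna_biotype_path: str | None = None
    regulons_path: str | None = None
    fasta_path: str | None = None
    motifs_path: str | None = None
    simulate: bool = False
    sim: dict = field(default_factory=dict)

    # thresholds (paper-mode defaults)
    p_de: float = PAPER_MODE["p_de"]
    fc: float = PAPER_MODE["fc"]
    r: float = PAPER_MODE["r"]
    p_coexpr: float = PAPER_MODE["p_coexpr"]
    p_enrich: float = PAPER_MODE["p_enrich"]
    fe: float = PAPER_MODE["fe"]
    pair_limit: int = PAPER_MODE["pair_limit"]
    triad_limit: int = PAPER_MODE["triad_limit"]

    # mode flags
    de_only_coexpr: bool = False
    tf_de_only: bool = False
    signed_fc: bool = False
    per_lncrna: bool = False
    targets_de_only: bool = True
    max_mismatch: int = 0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_de", "fc", "r", "p_coexpr", "p_enrich", "fe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.pair_limit < 1 or self.triad_limit < 1:
            raise ValueError("pair/triad limits must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
    return len(df)


def run(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline into ``outdir``; returns the run directory.

    Stages: (0) simulate or load inputs; (1) DE tests on mRNA and lncRNA
    matrices; (2) lncRNA-mRNA co-expression; (3) lncRNA functional
    annotation against the regulon collection; (4) lncRNA-TF pair scoring,
    100/10 selection, triad expansion, network export; (5) optional motif
    annotation. Writes ``manifest.json`` with the config echo, input
    checksums and per-stage row counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "inputs": {},
        "stages": {},
    }

    # ---- stage 0: inputs -------------------------------------------------
    if config.simulate:
        sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
        mrna, lnc, regulons, _truth = generate_dataset(sim_cfg)
        sequences = _truth.sequences
        motifs = _truth.motifs
    else:
        required = [config.mrna_path, config.lncrna_path, config.groups_path,
                    config.mrna_biotype_path, config.lncrna_biotype_path,
                    config.regulons_path]
        if any(p is None for p in required):
            raise ValueError("non-simulated run needs all input paths set")
        mrna = read_expression_matrix(
            config.mrna_path, config.groups_path, config.mrna_biotype_path
        )
        lnc = read_expression_matrix(
            config.lncrna_path, config.groups_path, config.lncrna_biotype_path
        )
        regulons = read_gmt(config.regulons_path)
        for p in required + [config.fasta_path, config.motifs_path]:
            if p is not None:
                manifest["inputs"][str(p)] = _sha256(Path(p))
        sequences = read_fasta(config.fasta_path) if config.fasta_path else {}
        motifs = read_motif_table(config.motifs_path) if config.motifs_path else {}

    # ---- stage 1: differential expression --------------------------------
    de_mrna = de_test(mrna, config.p_de, config.fc, signed_fc=config.signed_fc)
    de_lnc = de_test(lnc, config.p_de, config.fc, signed_fc=config.signed_fc)
    manifest["stages"]["de_mrna"] = _write_tsv(de_mrna, outdir / "de_mrna.tsv")
    manifest["stages"]["de_lncrna"] = _write_tsv(de_lnc, outdir / "de_lncrna.tsv")
    de_mrna_set = de_gene_set(de_mrna)
    de_lnc_set = de_gene_set(de_lnc)

    # ---- stage 2: co-expression ------------------------------------------
    lnc_in, mrna_in = lnc, mrna
    if config.de_only_coexpr:
        lnc_in = lnc.subset_genes(de_lnc_set)
        mrna_in = mrna.subset_genes(de_mrna_set)
    edges = coexpression_pairs(lnc_in, mrna_in, config.r, config.p_coexpr)
    manifest["stages"]["coexpression_edges"] = _write_tsv(edges, outdir / "coexpr_edges.tsv")
    if edges.empty:
        logger.warning("no co-expression edges at |r|>%s, p<%s; network will be empty",
                       config.r, config.p_coexpr)

    # universe for enrichment/pair scoring: expression-aware background
    universe = frozenset(mrna.gene_ids) & regulons.universe
    regulons_h = regulons.harmonize(universe) if universe else regulons

    # ---- stage 3: lncRNA functional annotation ---------------------------
    annot_frames = []
    if universe and not edges.empty:
        for lnc_id in sorted(edges["lncrna_id"].unique()):
            coexpr_in_universe = set(edges.loc[edges["lncrna_id"] == lnc_id, "mrna_id"]) & universe
            if not coexpr_in_universe:
                continue
            ann = annotate_lncrna(lnc_id, edges, regulons_h, config.p_enrich, config.fe)
            ann.insert(0, "lncrna_id", lnc_id)
            annot_frames.append(ann)
    annotations = (
        pd.concat(annot_frames, ignore_index=True) if annot_frames
        else pd.DataFrame(columns=["lncrna_id", "set_id", "k", "n", "K", "N",
                                   "p", "q", "fold_enrichment", "significant"])
    )
    manifest["stages"]["lncrna_annotations"] = _write_tsv(
        annotations, outdir / "lncrna_annotations.tsv"
    )

    # ---- stage 4: pair scoring, selection, triads, export ----------------
    tf_universe = sorted(regulons_h.sets)
    if config.tf_de_only:
        tf_universe = [tf for tf in tf_universe if tf in de_mrna_set]
    regulons_used = GeneSetCollection(
        sets={tf: regulons_h.sets[tf] for tf in tf_universe},
        universe=regulons_h.universe,
    ) if tf_universe else None

    empty_pairs = pd.DataFrame(
        columns=["lncrna_id", "tf_id", "k", "n", "K", "N", "p", "fold_enrichment"]
    )
    if regulons_used is not None and not edges.empty and universe:
        try:
            pairs = score_pairs(edges, regulons_used, universe)
        except ValueError:
            pairs = empty_pairs
    else:
        pairs = empty_pairs

    if not pairs.empty and sequences and motifs:
        hits = scan_all(sequences, motifs, config.max_mismatch)
        manifest["stages"]["motif_hits"] = _write_tsv(hits, outdir / "motif_hits.tsv")
        pairs = annotate_pairs(pairs, hits)

    pair_tier, triad_tier = select_pairs(pairs, config.pair_limit, config.triad_limit,
                                         per_lncrna=config.per_lncrna)
    manifest["stages"]["pairs_total"] = len(pairs)
    manifest["stages"]["pair_tier"] = _write_tsv(pair_tier, outdir / "pairs_top.tsv")

    de_filter = de_mrna_set if config.targets_de_only else None
    triads = (
        build_triads(triad_tier, edges, regulons_h, de_filter)
        if not triad_tier.empty else []
    )
    triad_rows = [
        {
            "lncrna_id": t.lncrna_id,
            "tf_id": t.tf_id,
            "n_targets": len(t.target_ids),
            "targets": ",".join(sorted(t.target_ids)),
            "pair_p": t.pair_p,
        }
        for t in triads
    ]
    triad_df = pd.DataFrame(
        triad_rows, columns=["lncrna_id", "tf_id", "n_targets", "targets", "pair_p"]
    )
    manifest["stages"]["triads"] = _write_tsv(triad_df, outdir / "triads.tsv")

    nodes, net_edges = export_network(
        triads, outdir / "network.sif", outdir / "network.graphml",
        outdir / "node_attrs.tsv",
    )
    audit_network(nodes, net_edges, edges, regulons_h)
    manifest["stages"]["network_nodes"] = len(nodes)
    manifest["stages"]["network_edges"] = len(net_edges)
    manifest["stages"]["de_mrna_called"] = int(len(de_mrna_set))
    manifest["stages"]["de_lncrna_called"] = int(len(de_lnc_set))

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline run complete: %s", outdir)
    return outdir
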