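"""IUPAC consensus-motif scanning of lncRNA sequences.

A lightweight surrogate for aligning lncRNAs against putative TF binding
sequences: every window of the lncRNA whose IUPAC-aware mismatch count
against the consensus stays within a budget is reported. Hits annotate
lncRNA-TF pairs as supporting evidence; they never gate or re-rank them.

Coordinates are 0-based half-open on the given (sense) strand; minus-strand
hits are computed on the reverse complement and reported in plus
coordinates. U is treated as T; N in the *sequence* never matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
SEQUENCE_ALPHABET = frozenset("ACGTUN")


@dataclass(frozen=True)
class MotifHit:
    lncrna_id: str
    tf_id: str
    motif: str
    start: int
    end: int
    mismatches: int
    strand: str


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _normalize_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - frozenset("ACGTN")
    if bad:
        raise ValueError(f"invalid sequence character(s): {sorted(bad)}")
    return seq


def _normalize_motif(motif: str) -> str:
    m = motif.upper().replace("U", "T")
    bad = set(m) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC motif character(s): {sorted(bad)}")
    return m


def _scan_one_strand(seq: str, motif: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(start, mismatches) for every window within the mismatch budget."""
    w = len(motif)
    allowed = [IUPAC[c] for c in motif]
    hits = []
    for start in range(len(seq) - w + 1):
        mm = 0
        for base, ok in zip(seq[start : start + w], allowed):
            # N in the sequence never matches, even against motif N
            if base == "N" or base not in ok:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            hits.append((start, mm))
    return hits


def scan(
    sequence: str,
    motif: str,
    max_mismatch: int = 0,
    both_strands: bool = False,
    lncrna_id: str = "",
    tf_id: str = "",
) -> list[MotifHit]:
    """All windows of ``sequence`` matching ``motif`` within ``max_mismatch``.

    lncRNA transcripts are single-stranded, so ``both_strands`` defaults
    off; when on, minus-strand hits are found on the reverse complement and
    reported in plus coordinates.
    """
    seq = _normalize_sequence(sequence)
    m = _normalize_motif(motif)
    if len(m) > len(seq):
        raise ValueError("motif longer than sequence")
    L, w = len(seq), len(m)
    hits = [
        MotifHit(lncrna_id, tf_id, motif, s, s + w, mm, "+")
        for s, mm in _scan_one_strand(seq, m, max_mismatch)
    ]
    if both_strands:
        for s, mm in _scan_one_strand(reverse_complement(seq), m, max_mismatch):
            # map reverse-complement window back to plus coordinates
            hits.append(MotifHit(lncrna_id, tf_id, motif, L - s - w, L - s, mm, "-"))
    return sorted(hits, key=lambda h: (h.start, h.strand))


def read_fasta(path: str | Path) -> dict[str, str]:
    """lncRNA sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_motif_table(path: str | Path) -> dict[str, str]:
    """TSV of (tf_id, motif) -> mapping; duplicate TFs are an error."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["tf_id", "motif"]:
        raise ValueError(f"{path}: expected header 'tf_id\\tmotif'")
    if df["tf_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate tf_id")
    return dict(zip(df["tf_id"], df["motif"]))


def scan_all(
    sequences: dict[str, str],
    motifs: dict[str, str],
    max_mismatch: int = 0,
    both_strands: bool = False,
) -> pd.DataFrame:
    """Scan every (lncRNA, TF motif) combination; tidy hit table."""
    rows = []
    for lnc in sorted(sequences):
        for tf in sorted(motifs):
            if len(motifs[tf]) > len(sequences[lnc]):
                continue
            for h in scan(sequences[lnc], motifs[tf], max_mismatch, both_strands, lnc, tf):
                rows.append(
                    {
                        "lncrna_id": h.lncrna_id, "tf_id": h.tf_id, "motif": h.motif,
                        "start": h.start, "end": h.end,
                        "mismatches": h.mismatches, "strand": h.strand,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["lncrna_id", "tf_id", "motif", "start", "end", "mismatches", "strand"],
    )


def annotate_pairs(pairs: pd.DataFrame, hits: pd.DataFrame) -> pd.DataFrame:
    """Attach ``motif_support`` (hit count per lncRNA-TF pair) to a pair table.

    Annotation only: the ranking columns are untouched.
    """
    if hits.empty:
        return pairs.assign(motif_support=0)
    counts = (
        hits.groupby(["lncrna_id", "tf_id"]).size().rename("motif_support").reset_index()
    )
    out = pairs.merge(counts, on=["lncrna_id", "tf_id"], how="left")
    out["motif_support"] = out["motif_support"].fillna(0).astype(int)
    return out
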