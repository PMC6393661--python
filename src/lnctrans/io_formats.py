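"""Readers and writers for the pipeline's external formats.

Expression matrices, sample groupings and gene biotypes travel as TSV;
gene sets and TF regulons as GMT; networks are exported as SIF + GraphML +
a node-attribute TSV for downstream visualization (e.g. Cytoscape).

All writers emit deterministically ordered, UTF-8, tab-separated text so
that repeated runs are byte-identical and round-trips can be byte-compared.
Missing values are an error, never silently imputed: the downstream
statistics assume complete matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("lnctrans")

GROUP_LABELS = frozenset({"case", "control"})
BIOTYPE_LABELS = frozenset({"mRNA", "lncRNA"})


# ---------------------------------------------------------------------------
# Validation errors
# ---------------------------------------------------------------------------

class ValidationError(ValueError):
    """Base class for malformed-input errors raised by this module."""


class DuplicateIdError(ValidationError):
    """A gene, sample or set identifier occurs more than once."""


class InvalidValueError(ValidationError):
    """A non-numeric, negative, missing or non-finite expression value."""


class GroupingError(ValidationError):
    """Sample grouping is missing, unknown, or not {case, control}."""


class BiotypeError(ValidationError):
    """A gene has a missing or unknown biotype label."""


class GmtFormatError(ValidationError):
    """A GMT line has fewer than three fields or repeats a set id."""


class NetworkConsistencyError(ValidationError):
    """An edge references a node absent from the node list."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """FPKM values for genes over labeled case/control samples.

    Parameters
    ----------
    values : pandas.DataFrame
        genes x samples, non-negative finite floats; row and column order is
        meaningful and preserved on round-trip.
    groups : mapping of sample id -> "case" | "control"
    biotype : mapping of gene id -> "mRNA" | "lncRNA"
    """

    values: pd.DataFrame
    groups: dict[str, str]
    biotype: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].tolist()
            raise DuplicateIdError(f"duplicate gene id(s): {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].tolist()
            raise DuplicateIdError(f"duplicate sample id(s): {dup}")
        arr = self.values.to_numpy()
        if arr.size:
            import numpy as np

            bad = ~np.isfinite(arr) | (arr < 0)
            if bad.any():
                gi, si = map(int, next(zip(*bad.nonzero())))
                raise InvalidValueError(
                    f"invalid FPKM value {arr[gi, si]!r} for gene "
                    f"{idx[gi]!r}, sample {cols[si]!r} (must be finite and >= 0)"
                )
        for s in cols:
            if s not in self.groups:
                raise GroupingError(f"sample {s!r} missing from groups file")
            if self.groups[s] not in GROUP_LABELS:
                raise GroupingError(
                    f"sample {s!r} has unknown group {self.groups[s]!r}"
                )
        present = {self.groups[s] for s in cols}
        if len(cols) and present != GROUP_LABELS:
            raise GroupingError(f"both case and control required, got {present}")
        for g in idx:
            if g not in self.biotype:
                raise BiotypeError(f"gene {g!r} missing from biotype file")
            if self.biotype[g] not in BIOTYPE_LABELS:
                raise BiotypeError(
                    f"gene {g!r} has unknown biotype {self.biotype[g]!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(
            values=self.values.loc[keep].copy(),
            groups=dict(self.groups),
            biotype={g: self.biotype[g] for g in keep},
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GO/KEGG terms or TF regulons) over a gene universe.

    ``sets`` maps set id -> (description, member genes). Members outside the
    declared universe are dropped with a warning at harmonization time; the
    paper-facing statistics all condition on the universe.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            u: set[str] = set()
            for _, genes in self.sets.values():
                u |= genes
            self.universe = frozenset(u)
        for sid, (_, genes) in self.sets.items():
            if not genes:
                raise GmtFormatError(f"gene set {sid!r} is empty")

    def harmonize(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Restrict every set (and the universe) to ``universe``.

        Genes falling outside are dropped with a logged warning; sets left
        empty are removed.
        """
        uni = frozenset(universe)
        new_sets: dict[str, tuple[str, frozenset[str]]] = {}
        for sid, (desc, genes) in self.sets.items():
            kept = genes & uni
            dropped = len(genes) - len(kept)
            if dropped:
                logger.warning(
                    "gene set %s: dropped %d gene(s) outside the universe",
                    sid, dropped,
                )
            if kept:
                new_sets[sid] = (desc, kept)
            else:
                logger.warning("gene set %s empty after harmonization; removed", sid)
        return GeneSetCollection(sets=new_sets, universe=uni)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]


# ---------------------------------------------------------------------------
# Expression matrix TSV I/O
# ---------------------------------------------------------------------------

def _read_two_column_tsv(path: str | Path, key: str, value: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != [key, value]:
        raise ValidationError(
            f"{path}: expected header '{key}\\t{value}', got {list(df.columns[:2])}"
        )
    if df[key].duplicated().any():
        dups = df.loc[df[key].duplicated(), key].tolist()
        raise DuplicateIdError(f"{path}: duplicate {key}(s): {dups}")
    return dict(zip(df[key], df[value]))


def read_expression_matrix(
    path: str | Path,
    groups_path: str | Path,
    biotype_path: str | Path,
) -> ExpressionMatrix:
    """Read an FPKM matrix plus its sample-group and gene-biotype maps.

    The expression TSV has a header row of sample ids with ``gene_id`` as the
    first column. Row/column order is preserved. Each distinct malformation
    raises a distinct :class:`ValidationError` subclass.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.columns[0] != "gene_id":
        raise ValidationError(f"{path}: first column must be 'gene_id'")
    raw = raw.set_index("gene_id")
    if raw.isna().any().any():
        r, c = next(zip(*raw.isna().to_numpy().nonzero()))
        raise InvalidValueError(
            f"{path}: missing value for gene {raw.index[int(r)]!r}, "
            f"sample {raw.columns[int(c)]!r}"
        )
    try:
        values = raw.astype(float)
    except ValueError:
        for c in raw.columns:
            bad = pd.to_numeric(raw[c], errors="coerce").isna()
            if bad.any():
                g = raw.index[bad.to_numpy().nonzero()[0][0]]
                raise InvalidValueError(
                    f"{path}: non-numeric value {raw.loc[g, c]!r} for gene "
                    f"{g!r}, sample {c!r}"
                ) from None
        raise
    groups = _read_two_column_tsv(groups_path, "sample_id", "group")
    biotype = _read_two_column_tsv(biotype_path, "gene_id", "biotype")
    return ExpressionMatrix(values=values, groups=groups, biotype=biotype)


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    groups_path: str | Path | None = None,
    biotype_path: str | Path | None = None,
) -> None:
    """Write the matrix (and optionally groups/biotype maps) as TSV."""
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")
    if groups_path is not None:
        with open(groups_path, "w", encoding="utf-8") as fh:
            fh.write("sample_id\tgroup\n")
            for s in matrix.sample_ids:
                fh.write(f"{s}\t{matrix.groups[s]}\n")
    if biotype_path is not None:
        with open(biotype_path, "w", encoding="utf-8") as fh:
            fh.write("gene_id\tbiotype\n")
            for g in matrix.gene_ids:
                fh.write(f"{g}\t{matrix.biotype[g]}\n")


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file: ``set_id <TAB> description <TAB> gene1 <TAB> ...``.

    Duplicate genes within one line are collapsed; a repeated set id or a
    line with fewer than three fields is an error. The universe defaults to
    the union of all sets.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            sid, desc, *genes = fields
            if sid in sets:
                raise GmtFormatError(f"{path}:{lineno}: duplicate set id {sid!r}")
            members = frozenset(g for g in genes if g)
            if not members:
                raise GmtFormatError(f"{path}:{lineno}: set {sid!r} has no genes")
            sets[sid] = (desc, members)
    return GeneSetCollection(
        sets=sets,
        universe=frozenset(universe) if universe is not None else frozenset(),
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write gene sets as GMT, sets and members sorted for byte-stability."""
    with open(path, "w", encoding="utf-8") as fh:
        for sid in sorted(collection.sets):
            desc, genes = collection.sets[sid]
            fh.write("\t".join([sid, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Network export (SIF + GraphML + node attributes)
# ---------------------------------------------------------------------------

NODE_TYPES = frozenset({"lncRNA", "TF", "target"})


def write_network(
    nodes: Sequence[tuple[str, str]],
    edges: Sequence[tuple[str, str, str, float]],
    path_sif: str | Path,
    path_graphml: str | Path,
    path_attrs: str | Path,
) -> None:
    """Export a typed network for visualization tools.

    ``nodes`` are (node_id, type) with type in {lncRNA, TF, target};
    ``edges`` are (source, interaction, target, score) where interaction is
    ``coexpression`` for lncRNA-TF / lncRNA-target links and ``regulates``
    for TF-target links. Output line order is sorted by key so repeated
    writes are byte-identical.
    """
    node_types = dict(nodes)
    if len(node_types) != len(nodes):
        raise DuplicateIdError("duplicate node id in node list")
    for nid, ntype in nodes:
        if ntype not in NODE_TYPES:
            raise NetworkConsistencyError(f"node {nid!r} has unknown type {ntype!r}")
    for src, _, dst, _ in edges:
        if src not in node_types or dst not in node_types:
            raise NetworkConsistencyError(
                f"edge ({src!r}, {dst!r}) references a node absent from the node list"
            )

    sorted_edges = sorted(edges, key=lambda e: (e[0], e[1], e[2]))
    with open(path_sif, "w", encoding="utf-8") as fh:
        for src, rel, dst, _ in sorted_edges:
            fh.write(f"{src}\t{rel}\t{dst}\n")

    with open(path_attrs, "w", encoding="utf-8") as fh:
        fh.write("node_id\ttype\n")
        for nid in sorted(node_types):
            fh.write(f"{nid}\t{node_types[nid]}\n")

    g = nx.Graph()
    for nid in sorted(node_types):
        g.add_node(nid, type=node_types[nid])
    for src, rel, dst, score in sorted_edges:
        g.add_edge(src, dst, interaction=rel, score=float(score))
    nx.write_graphml(g, path_graphml)


def read_sif(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a SIF file back as (source, interaction, target) triples."""
    out: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            src, rel, dst = line.split("\t")
            out.append((src, rel, dst))
    return out
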