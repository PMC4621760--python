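"""Readers and writers for the file formats the pipeline touches.

Coordinate conventions
----------------------
All internal coordinates are 1-based inclusive (the GFF3 convention).
BED input (0-based half-open) is converted on read:
``start_internal = bed_start + 1``, ``end_internal = bed_end``.
Gene order within a chromosome is the rank by start coordinate after
sorting, ties broken by gene id.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """A file violated the expected syntax or invariants."""


# ---------------------------------------------------------------------------
# FASTA


@dataclass
class SeqRecord:
    """A named sequence (nucleotide or amino acid), uppercased."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord` in file order.

    Sequences are uppercased and whitespace-stripped.  A file whose first
    non-blank line does not start with ``>`` is rejected, as is an empty
    file or a header with no sequence.
    """
    with open(path) as handle:
        text = handle.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FormatError(f"{path}: line {lineno}: expected FASTA header '>'")
        break
    else:
        raise FormatError(f"{path}: empty FASTA file")
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = str(rec.seq).replace(" ", "").upper()
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty id")
        if not seq:
            raise FormatError(f"{path}: FASTA record {rec.id!r} has no sequence")
        records.append(SeqRecord(id=rec.id, sequence=seq, description=rec.description))
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as out:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            out.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models / GFF3


@dataclass
class GeneModel:
    """One gene: chromosome interval, strand, exons and first coding base.

    ``cds_start`` is the chromosome coordinate of the first coding base:
    the minimum CDS coordinate on the + strand, the maximum on the −
    strand (both 1-based).
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: end < start ({self.end} < {self.start})"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")
        if self.cds_start is not None and not (self.start <= self.cds_start <= self.end):
            raise FormatError(f"gene {self.gene_id}: cds_start outside gene span")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneCatalog:
    """Gene models indexed by id, with per-chromosome order lists.

    ``family_ids`` marks the subset under study (the Aux/IAA members);
    ``order`` maps chromosome -> gene ids sorted by start (ties by id).
    """

    genes: dict[str, GeneModel]
    family_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        missing = self.family_ids - set(self.genes)
        if missing:
            raise FormatError(f"family ids absent from catalog: {sorted(missing)}")
        self._build_order()

    def _build_order(self) -> None:
        by_chrom: dict[str, list[str]] = {}
        for gid, g in self.genes.items():
            by_chrom.setdefault(g.chromosome, []).append(gid)
        self.order: dict[str, list[str]] = {
            c: sorted(ids, key=lambda i: (self.genes[i].start, i))
            for c, ids in sorted(by_chrom.items())
        }
        self._index: dict[str, int] = {}
        for ids in self.order.values():
            for i, gid in enumerate(ids):
                self._index[gid] = i

    @property
    def chromosomes(self) -> list[str]:
        return list(self.order)

    def order_index(self, gene_id: str) -> int:
        """Rank of the gene within its chromosome (0-based)."""
        return self._index[gene_id]

    def family_genes(self):
        return [self.genes[g] for g in sorted(self.family_ids)]


def read_gff3(path, family_ids=None) -> GeneCatalog:
    """Load gene/mRNA/exon/CDS features from a GFF3 file into a catalog."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        if g.end < g.start:
            raise FormatError(f"{path}: gene {g.id}: end < start")
        exons = []
        cds_coords = []
        for child in db.children(g.id, featuretype=("exon", "CDS")):
            if child.end < child.start:
                raise FormatError(f"{path}: feature under {g.id}: end < start")
            if child.featuretype == "exon":
                exons.append((child.start, child.end))
            else:
                cds_coords.extend([child.start, child.end])
        cds_start = None
        if cds_coords:
            cds_start = min(cds_coords) if g.strand == "+" else max(cds_coords)
        genes[g.id] = GeneModel(
            gene_id=g.id,
            chromosome=g.seqid,
            start=g.start,
            end=g.end,
            strand=g.strand,
            exons=exons,
            cds_start=cds_start,
        )
    # a CDS feature whose parent chain reaches no gene is an annotation error
    gene_ids = set(genes)
    for c in db.features_of_type("CDS"):
        parents = {p.id for p in db.parents(c.id)}
        mrna_parents = {p.id for p in db.parents(c.id, featuretype="mRNA")}
        for m in list(mrna_parents):
            parents |= {p.id for p in db.parents(m)}
        if not parents & gene_ids:
            raise FormatError(f"{path}: CDS {c.id} has no parent gene")
    return GeneCatalog(genes=genes, family_ids=set(family_ids or ()))


# ---------------------------------------------------------------------------
# BED (transposable-element annotations)


@dataclass
class TeAnnotation:
    """A transposable-element interval, 1-based inclusive internally."""

    chromosome: str
    start: int
    end: int
    te_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"TE {self.te_id or '?'}: start > end")


def read_bed(path) -> list[TeAnnotation]:
    """Read a >=3 column BED file, converting to 1-based inclusive."""
    out = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                bed_start, bed_end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if bed_start < 0:
                raise FormatError(f"{path}: line {lineno}: negative start")
            if bed_end <= bed_start:
                raise FormatError(f"{path}: line {lineno}: empty or inverted interval")
            name = cols[3] if len(cols) > 3 else ""
            out.append(TeAnnotation(cols[0], bed_start + 1, bed_end, name))
    return out


def write_bed(tes, path) -> None:
    with open(path, "w") as out:
        for te in tes:
            out.write(f"{te.chromosome}\t{te.start - 1}\t{te.end}\t{te.te_id}\n")


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree) -> str:
    """Serialize an ultrametric tree (see :mod:`auxiaa.phylogeny`) to Newick.

    Branch lengths are parent height minus child height; leaves carry their
    labels, internal nodes carry bootstrap support if annotated.  Duplicate
    leaf labels are rejected.
    """
    labels = tree.leaf_labels()
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate leaf labels in tree")

    def render(node, parent_height) -> str:
        blen = parent_height - node.height
        if node.is_leaf():
            return f"{node.label}:{float(blen)}"
        inner = ",".join(render(c, node.height) for c in node.children)
        sup = "" if node.support is None else f"{node.support:.10g}"
        return f"({inner}){sup}:{float(blen)}"

    root = tree.root
    if root.is_leaf():
        return f"{root.label}:{float(root.height)};"
    inner = ",".join(render(c, root.height) for c in root.children)
    sup = "" if root.support is None else f"{root.support:.10g}"
    return f"({inner}){sup};"


# ---------------------------------------------------------------------------
# Numeric tables


def read_matrix(path) -> pd.DataFrame:
    """Read a genes x samples TSV with a header row and gene-id first column.

    Every cell must be numeric and present; duplicate gene ids and ragged
    rows are rejected.
    """
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        ncol = len(header)
        for lineno, line in enumerate(handle, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != ncol:
                raise FormatError(f"{path}: line {lineno}: ragged row")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids {dupes}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = df.index[bad.isna()][0]
            raise FormatError(
                f"{path}: non-numeric or missing value at row {row!r}, column {col!r}"
            )
        df[col] = bad
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
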