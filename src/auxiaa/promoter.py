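"""Promoter extraction and degenerate (IUPAC) cis-element scanning.

Promoters are the 1,000 bp upstream of the first coding base
(``cds_start``), read 5'->3' relative to the gene: for a + strand gene the
bases ``[cds_start - length, cds_start - 1]``, for a − strand gene the
reverse complement of ``[cds_start + 1, cds_start + length]``.  Promoter
position 1 is the farthest-upstream base.  Scanning covers both strands; a
− strand hit is reported at the forward-coordinate of its match start.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

from .formats import FormatError, GeneCatalog

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterRecord:
    gene_id: str
    sequence: str
    chromosome: str
    interval: tuple[int, int]  # genomic, 1-based inclusive
    strand: str
    truncated: bool = False


@dataclass(frozen=True)
class CisElement:
    element_id: str
    name: str
    pattern: str

    def __post_init__(self) -> None:
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise FormatError(
                f"element {self.element_id}: invalid IUPAC letter(s) {sorted(bad)}"
            )
        if not self.pattern:
            raise FormatError(f"element {self.element_id}: empty pattern")


@dataclass(frozen=True)
class ElementHit:
    gene_id: str
    element_id: str
    position: int  # 1-based within the promoter
    strand: str


def default_element_library() -> list[CisElement]:
    """Packaged PLACE-nomenclature element library (data/elements.tsv)."""
    return load_element_library(
        importlib.resources.files("auxiaa.data") / "elements.tsv"
    )


def load_element_library(path) -> list[CisElement]:
    out = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("element_id\t"):
                continue
            eid, name, pattern = line.split("\t")[:3]
            out.append(CisElement(eid, name, pattern.upper()))
    return out


def extract_promoters(
    genome: dict[str, str], catalog: GeneCatalog, length: int = 1000
) -> list[PromoterRecord]:
    """Strand-aware upstream regions for every family gene.

    Regions running off a chromosome end are truncated and flagged; a gene
    whose promoter would be empty raises an error.
    """
    out = []
    for gene in catalog.family_genes():
        if gene.chromosome not in genome:
            raise KeyError(f"chromosome {gene.chromosome} absent from genome")
        chrom_seq = genome[gene.chromosome]
        if gene.cds_start is None:
            raise ValueError(f"gene {gene.gene_id}: no CDS; promoter undefined")
        if gene.strand == "+":
            lo = max(1, gene.cds_start - length)
            hi = gene.cds_start - 1
            if hi < lo:
                raise ValueError(
                    f"gene {gene.gene_id}: no upstream sequence before cds_start"
                )
            seq = chrom_seq[lo - 1 : hi]
            truncated = (hi - lo + 1) < length
        else:
            lo = gene.cds_start + 1
            hi = min(len(chrom_seq), gene.cds_start + length)
            if hi < lo:
                raise ValueError(
                    f"gene {gene.gene_id}: no upstream sequence after cds_start"
                )
            seq = revcomp(chrom_seq[lo - 1 : hi])
            truncated = (hi - lo + 1) < length
        out.append(
            PromoterRecord(
                gene_id=gene.gene_id,
                sequence=seq.upper(),
                chromosome=gene.chromosome,
                interval=(lo, hi),
                strand=gene.strand,
                truncated=truncated,
            )
        )
    return out


def _iupac_match_positions(seq: str, pattern: str) -> list[int]:
    """1-based start positions where the IUPAC pattern matches exactly."""
    sets = [IUPAC[c] for c in pattern]
    m = len(sets)
    out = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        ok = True
        for c, allowed in zip(window, sets):
            if c not in allowed:
                ok = False
                break
        if ok:
            out.append(i + 1)
    return out


def scan_elements(
    promoter: PromoterRecord, library: list[CisElement]
) -> list[ElementHit]:
    """All (overlapping) matches of each element on both strands.

    A + hit matches the promoter sequence directly; a − hit is a position
    where the reverse complement of the pattern matches the forward
    sequence, reported at the forward match start.
    """
    seq = promoter.sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise FormatError(
            f"promoter {promoter.gene_id}: invalid nucleotide(s) {sorted(bad)}"
        )
    hits = []
    for el in library:
        pat = el.pattern.upper()
        for pos in _iupac_match_positions(seq, pat):
            hits.append(ElementHit(promoter.gene_id, el.element_id, pos, "+"))
        for pos in _iupac_match_positions(seq, revcomp(pat)):
            hits.append(ElementHit(promoter.gene_id, el.element_id, pos, "-"))
    return hits


def element_presence_table(hits, gene_ids, library):
    """Zero-filled gene x element hit-count table (pandas DataFrame)."""
    import pandas as pd

    element_ids = [e.element_id for e in library]
    table = pd.DataFrame(0, index=list(gene_ids), columns=element_ids, dtype=int)
    for h in hits:
        if h.gene_id in table.index and h.element_id in table.columns:
            table.loc[h.gene_id, h.element_id] += 1
    return table
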