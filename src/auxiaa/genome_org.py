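"""Chromosome distribution, tandem clusters and exon-intron structure.

A *tandem cluster* is a maximal run of family genes on one chromosome in
which consecutive members are separated by at most ``max_intervening``
non-family genes (by gene-order index) and at most ``max_gap`` base pairs.
The paper-style reports list clusters but never state a rule; both
parameters are exposed and default to 1 intervening gene / 100 kb.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats import FormatError, GeneCatalog, GeneModel


def chromosome_distribution(catalog: GeneCatalog):
    """Family-gene counts per chromosome.

    Returns ``(counts, absent)``: chromosomes with zero family genes are
    omitted from ``counts`` but listed in ``absent``.
    """
    counts: dict[str, int] = {}
    for gid in catalog.family_ids:
        chrom = catalog.genes[gid].chromosome
        counts[chrom] = counts.get(chrom, 0) + 1
    absent = [c for c in catalog.chromosomes if c not in counts]
    return dict(sorted(counts.items())), sorted(absent)


@dataclass
class TandemCluster:
    chromosome: str
    member_ids: list[str]
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("a tandem cluster needs at least two members")


def detect_tandem_clusters(
    catalog: GeneCatalog, max_intervening: int = 1, max_gap: int = 100_000
) -> list[TandemCluster]:
    """Maximal runs of family genes satisfying the adjacency rule.

    Singletons are excluded; clusters are disjoint and order-maximal
    (no neighbor can be appended without violating the rule).
    """
    clusters = []
    for chrom, order in catalog.order.items():
        fam = [
            (i, gid) for i, gid in enumerate(order) if gid in catalog.family_ids
        ]
        run: list[tuple[int, str]] = []
        for item in fam:
            if run:
                prev_i, prev_id = run[-1]
                intervening = item[0] - prev_i - 1
                gap = catalog.genes[item[1]].start - catalog.genes[prev_id].end
                if intervening <= max_intervening and gap <= max_gap:
                    run.append(item)
                    continue
                if len(run) >= 2:
                    clusters.append(_make_cluster(catalog, chrom, run))
                run = []
            run.append(item)
        if len(run) >= 2:
            clusters.append(_make_cluster(catalog, chrom, run))
    return clusters


def _make_cluster(catalog, chrom, run) -> TandemCluster:
    ids = [gid for _, gid in run]
    start = min(catalog.genes[g].start for g in ids)
    end = max(catalog.genes[g].end for g in ids)
    return TandemCluster(chromosome=chrom, member_ids=ids, span=(start, end))


def intron_structure(gene: GeneModel):
    """Introns as the gaps between consecutive exons (1-based inclusive)."""
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        if s2 <= e1:
            raise FormatError(f"gene {gene.gene_id}: overlapping exons")
    introns = [
        (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(gene.exons, gene.exons[1:])
    ]
    return introns, len(introns)
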