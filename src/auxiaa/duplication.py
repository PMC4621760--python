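"""Duplication analysis: collinearity, mode classification, Ka/Ks, dating.

Duplicate pairs are classified by precedence into WGD/segmental (anchored
inside a collinear block), tandem (same tandem cluster), transposed
(flanked by transposable elements on both sides) or dispersed.  Synonymous
and nonsynonymous substitution rates are estimated with the Nei-Gojobori
(1986) method — per-position synonymous-site fractions with stop-excluded
renormalization, pathway averaging for multi-site codon differences, and
Jukes-Cantor correction — and synonymous divergence is converted to time
as ``T = Ks / (2 * lambda) * 1e-6`` Mya with a clock rate of
``lambda = 6.1e-9`` substitutions/site/year.  Ks thresholds of 0.3 and 1.3
bin pairs into the *Glycine* WGD, legume WGD and gamma WGT eras.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .formats import GeneModel, TeAnnotation

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
STOP_CODONS = set(_STANDARD.stop_codons)
CODON_TO_AA = dict(_STANDARD.forward_table)
for _c in STOP_CODONS:
    CODON_TO_AA[_c] = "*"
SENSE_CODONS = sorted(set(CODON_TO_AA) - STOP_CODONS)
BASES = "ACGT"
GAP_CODON = "---"


class SaturationError(ValueError):
    """Observed proportion of differences >= 3/4: Jukes-Cantor undefined."""


# ---------------------------------------------------------------------------
# Collinearity


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    order_a: int
    order_b: int

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"anchor pairs a gene with itself: {self.gene_a}")


@dataclass
class CollinearBlock:
    block_id: str
    anchors: list[AnchorPair]
    chrom_a: str
    chrom_b: str
    orientation: str  # same | inverted

    @property
    def genes(self) -> set[str]:
        out = set()
        for a in self.anchors:
            out.add(a.gene_a)
            out.add(a.gene_b)
        return out


def _best_chain(anchors: list[AnchorPair], sign: int, max_index_gap: int):
    """Longest chain with strictly increasing order_a and strictly
    monotone order_b (direction given by sign), index gaps bounded."""
    order = sorted(range(len(anchors)), key=lambda k: (anchors[k].order_a, anchors[k].order_b))
    best_len = [1] * len(anchors)
    prev = [-1] * len(anchors)
    for pi, i in enumerate(order):
        ai = anchors[i]
        for j in (order[k] for k in range(pi)):
            aj = anchors[j]
            if aj.order_a >= ai.order_a:
                continue
            if ai.order_a - aj.order_a > max_index_gap:
                continue
            db = sign * (ai.order_b - aj.order_b)
            if db <= 0 or db > max_index_gap:
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = max(range(len(anchors)), key=lambda k: best_len[k])
    chain = []
    k = end
    while k != -1:
        chain.append(k)
        k = prev[k]
    chain.reverse()
    return chain


def detect_collinear_blocks(
    anchors: list[AnchorPair], min_anchors: int = 5, max_index_gap: int = 25
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks per chromosome pair.

    Dynamic programming finds the longest chain (strictly monotone in both
    gene orders, either direction, with index gaps bounded on both
    genomes); chains are extracted greedily, each anchor serving at most
    one block, until no chain reaches ``min_anchors``.
    """
    groups: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        groups.setdefault((a.chrom_a, a.chrom_b), []).append(a)
    blocks = []
    counter = 0
    for (ca, cb), pool in sorted(groups.items()):
        pool = list(pool)
        while len(pool) >= min_anchors:
            up = _best_chain(pool, +1, max_index_gap)
            down = _best_chain(pool, -1, max_index_gap)
            chain, orient = (
                (up, "same") if len(up) >= len(down) else (down, "inverted")
            )
            if len(chain) < min_anchors:
                break
            counter += 1
            chosen = [pool[k] for k in chain]
            blocks.append(
                CollinearBlock(
                    block_id=f"B{counter}",
                    anchors=chosen,
                    chrom_a=ca,
                    chrom_b=cb,
                    orientation=orient,
                )
            )
            used = set(chain)
            pool = [a for k, a in enumerate(pool) if k not in used]
    return blocks


# ---------------------------------------------------------------------------
# Transposed-duplication test


def flanking_te_test(
    gene: GeneModel, te_annotations: list[TeAnnotation], window: int = 10_000
):
    """True iff the gene has >=1 TE within ``window`` bp on *both* flanks.

    Returns ``(flag, nearest)`` where nearest lists the closest upstream
    and downstream TE (chromosome order, strand-agnostic).
    """
    up = [
        te
        for te in te_annotations
        if te.chromosome == gene.chromosome
        and te.end < gene.start
        and gene.start - te.end <= window
    ]
    down = [
        te
        for te in te_annotations
        if te.chromosome == gene.chromosome
        and te.start > gene.end
        and te.start - gene.end <= window
    ]
    nearest = []
    if up:
        nearest.append(max(up, key=lambda t: t.end))
    if down:
        nearest.append(min(down, key=lambda t: t.start))
    return bool(up) and bool(down), nearest


# ---------------------------------------------------------------------------
# Mode classification


@dataclass
class DuplicationCall:
    gene_id: str
    mode: str  # wgd_segmental | tandem | transposed | dispersed
    evidence: dict = field(default_factory=dict)


def classify_duplication_mode(
    gene_id: str,
    family_ids: set[str],
    blocks: list[CollinearBlock],
    clusters,
    te_flags: dict[str, bool],
) -> DuplicationCall:
    """Assign exactly one duplication mode by precedence:

    1. anchored inside a collinear block -> wgd_segmental
    2. member of a tandem cluster -> tandem
    3. has a family homolog elsewhere, outside all blocks/clusters, and
       TE-flanked on both sides -> transposed
    4. otherwise -> dispersed
    """
    for b in blocks:
        if gene_id in b.genes:
            return DuplicationCall(gene_id, "wgd_segmental", {"block_id": b.block_id})
    for k, c in enumerate(clusters):
        if gene_id in c.member_ids:
            return DuplicationCall(gene_id, "tandem", {"cluster_index": k})
    has_homolog = len(family_ids - {gene_id}) > 0
    if has_homolog and te_flags.get(gene_id, False):
        return DuplicationCall(gene_id, "transposed", {"te_flanked": True})
    return DuplicationCall(gene_id, "dispersed", {})


def classify_all(family_ids, blocks, clusters, te_flags) -> dict[str, DuplicationCall]:
    return {
        g: classify_duplication_mode(g, set(family_ids), blocks, clusters, te_flags)
        for g in sorted(family_ids)
    }


# ---------------------------------------------------------------------------
# Codon alignments


@dataclass
class CodonAlignment:
    """Paired codon columns; a column is (codon_a, codon_b), '---' = gap."""

    id_a: str
    id_b: str
    columns: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for ca, cb in self.columns:
            for c in (ca, cb):
                if c == GAP_CODON:
                    continue
                if len(c) != 3 or set(c) - set(BASES):
                    raise ValueError(f"bad codon {c!r}")
                if c in STOP_CODONS:
                    raise ValueError(f"internal stop codon {c}")

    def ungapped(self):
        return [(a, b) for a, b in self.columns if GAP_CODON not in (a, b)]


def back_translate(
    aligned_a: str, aligned_b: str, cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b"
) -> CodonAlignment:
    """Thread the two CDSs through a gapped protein alignment.

    Each CDS must be exactly 3x its ungapped protein length and translate
    to that protein under the standard code (internal stops rejected).
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    cols = []
    for seq_aln, cds, name in ((aligned_a, cds_a, id_a), (aligned_b, cds_b, id_b)):
        prot = seq_aln.replace("-", "")
        if len(cds) != 3 * len(prot):
            raise ValueError(
                f"{name}: CDS length {len(cds)} != 3 x protein length {len(prot)}"
            )
        for i, aa in enumerate(prot):
            codon = cds[3 * i : 3 * i + 3]
            if codon in STOP_CODONS:
                raise ValueError(f"{name}: internal stop codon at residue {i + 1}")
            if CODON_TO_AA.get(codon) != aa:
                raise ValueError(
                    f"{name}: codon {codon} at residue {i + 1} does not encode {aa}"
                )
    pa = pb = 0
    for ra, rb in zip(aligned_a, aligned_b):
        ca = cds_a[3 * pa : 3 * pa + 3] if ra != "-" else GAP_CODON
        cb = cds_b[3 * pb : 3 * pb + 3] if rb != "-" else GAP_CODON
        if ra != "-":
            pa += 1
        if rb != "-":
            pb += 1
        cols.append((ca, cb))
    return CodonAlignment(id_a=id_a, id_b=id_b, columns=cols)


# ---------------------------------------------------------------------------
# Nei-Gojobori counting


def ng_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts of one sense codon.

    At each position the synonymous fraction is the number of single-base
    changes preserving the amino acid divided by the number of changes not
    creating a stop codon (stop-excluded renormalization); s sums the
    fractions, n = 3 - s.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    if codon not in CODON_TO_AA:
        raise ValueError(f"not a codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def _pathways(codon_a: str, codon_b: str):
    """All single-step pathways between two codons, as lists of
    (syn_steps, nonsyn_steps, blocked) per permutation of changed sites."""
    diff = [p for p in range(3) if codon_a[p] != codon_b[p]]
    out = []
    for order in itertools.permutations(diff):
        cur = codon_a
        sd = nd = 0
        blocked = False
        for p in order:
            nxt = cur[:p] + codon_b[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                nd += 1  # only used in the all-blocked fallback
            elif CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        out.append((sd, nd, blocked))
    return out


def ng_codon_diff(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Observed synonymous/nonsynonymous differences between two codons.

    Multi-site differences are averaged over all orderings of single-base
    steps, excluding pathways passing through stop codons; if every
    pathway is blocked, the average runs over all pathways with stop steps
    counted as nonsynonymous (see :func:`ng_codon_diff_flagged`).
    """
    sd, nd, _ = ng_codon_diff_flagged(codon_a, codon_b)
    return sd, nd


def ng_codon_diff_flagged(codon_a: str, codon_b: str):
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c in STOP_CODONS or c not in CODON_TO_AA:
            raise ValueError(f"not a sense codon: {c!r}")
    if codon_a == codon_b:
        return 0.0, 0.0, False
    paths = _pathways(codon_a, codon_b)
    open_paths = [(s, n) for s, n, blocked in paths if not blocked]
    if open_paths:
        sd = sum(s for s, _ in open_paths) / len(open_paths)
        nd = sum(n for _, n in open_paths) / len(open_paths)
        return sd, nd, False
    sd = sum(s for s, _, _ in paths) / len(paths)
    nd = sum(n for _, n, _ in paths) / len(paths)
    return sd, nd, True


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: float | None
    S: float
    N: float
    Sd: float
    Nd: float
    n_codons: int
    blocked_pathways: int = 0


def _jukes_cantor(p: float) -> float:
    import math

    if p >= 0.75:
        raise SaturationError(
            f"proportion of differences {p:.4f} >= 3/4; distance undefined"
        )
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng_kaks(alignment: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori Ka/Ks over the ungapped codon columns of an alignment.

    S and N are the means of the two sequences' per-codon site sums;
    pS = sum(Sd)/S and pN = sum(Nd)/N are Jukes-Cantor corrected to
    Ks and Ka.  The ratio is defined only when Ks > 0.
    """
    cols = alignment.ungapped()
    if not cols:
        raise ValueError("no ungapped codon columns")
    Sa = Na = Sb = Nb = 0.0
    Sd = Nd = 0.0
    blocked = 0
    for ca, cb in cols:
        sa, na = ng_site_counts(ca)
        sb, nb = ng_site_counts(cb)
        Sa += sa
        Na += na
        Sb += sb
        Nb += nb
        sd, nd, was_blocked = ng_codon_diff_flagged(ca, cb)
        Sd += sd
        Nd += nd
        blocked += was_blocked
    S = (Sa + Sb) / 2.0
    N = (Na + Nb) / 2.0
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks = _jukes_cantor(pS)
    ka = _jukes_cantor(pN)
    ratio = ka / ks if ks > 0 else None
    return KaKsResult(
        ka=ka, ks=ks, ratio=ratio, S=S, N=N, Sd=Sd, Nd=Nd,
        n_codons=len(cols), blocked_pathways=blocked,
    )


# ---------------------------------------------------------------------------
# Dating


@dataclass(frozen=True)
class DatingParams:
    """Clock rate (substitutions/site/year) and Ks event-bin boundaries."""

    rate: float = 6.1e-9
    glycine_max_ks: float = 0.3
    gamma_min_ks: float = 1.3

    def __post_init__(self) -> None:
        if not (0 < self.glycine_max_ks < self.gamma_min_ks):
            raise ValueError("require 0 < glycine_max_ks < gamma_min_ks")


def divergence_time(ks: float, params: DatingParams = DatingParams()) -> float:
    """T = Ks / (2 * rate) * 1e-6, in millions of years (Mya)."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * params.rate) * 1e-6


def assign_wgd_event(ks: float, params: DatingParams = DatingParams()) -> str:
    """Bin a pair's Ks into the WGD era it postdates.

    Ks < 0.3 -> *Glycine* WGD; 0.3 <= Ks <= 1.3 -> legume WGD;
    Ks > 1.3 -> gamma WGT (boundaries inclusive to the legume bin).
    """
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    if ks < params.glycine_max_ks:
        return "glycine_wgd"
    if ks <= params.gamma_min_ks:
        return "legume_wgd"
    return "gamma_wgt"
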