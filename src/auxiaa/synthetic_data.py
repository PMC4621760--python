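"""Synthetic fixture generation for the whole survey pipeline.

The packaged catalogs transcribe the printed Aux/IAA gene lists for
chickpea (22 genes) and soybean (63 genes): chromosome assignments,
tandem clusters, non-canonical (degron-less) members, duplication-mode
labels, paralog pairings and expression-divergence labels.  The
generators then build a self-consistent dataset around a catalog:

* proteins carrying the four conserved motif blocks (motif II only for
  canonical members), paralogs derived from a shared ancestor;
* a genome with genes placed per catalog order, cluster members adjacent,
  each WGD-labeled gene embedded in a collinear anchor chain, transposed
  genes flanked by transposable elements, and promoters with planted
  cis-elements (recorded in a planting manifest);
* codon pairs diverged to a target synonymous divergence under a chosen
  Ka/Ks (omega);
* an expression count matrix with gamma-Poisson noise where catalog
  "conserved" pairs share latent tissue profiles at high correlation and
  "diverged" pairs at low correlation.

Every generator is deterministic under the config seed.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import duplication as dup
from . import family_scan, genome_org, promoter
from .duplication import (
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    AnchorPair,
)
from .formats import GeneCatalog, GeneModel, SeqRecord, TeAnnotation

BASES = "ACGT"
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

_CODONS_FOR = {}
for _c, _a in CODON_TO_AA.items():
    if _a != "*":
        _CODONS_FOR.setdefault(_a, []).append(_c)
for _a in _CODONS_FOR:
    _CODONS_FOR[_a].sort()


class CatalogError(ValueError):
    """Packaged catalog failed its integrity checks."""


# ---------------------------------------------------------------------------
# Paper catalog


@dataclass(frozen=True)
class CatalogRecord:
    gene_id: str
    chromosome: str
    cluster_id: str
    canonical_status: str
    mode: str
    pair_partner: str
    expression_class: str


@dataclass
class PaperCatalog:
    species: str
    records: list[CatalogRecord]

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    @property
    def by_id(self) -> dict[str, CatalogRecord]:
        return {r.gene_id: r for r in self.records}

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for r in self.records:
            if r.cluster_id:
                out.setdefault(r.cluster_id, []).append(r.gene_id)
        return out

    def pairs(self) -> list[tuple[str, str]]:
        seen = set()
        out = []
        for r in self.records:
            if r.pair_partner and r.gene_id not in seen:
                out.append((r.gene_id, r.pair_partner))
                seen.update((r.gene_id, r.pair_partner))
        return out

    def expression_pairs(self) -> list[tuple[str, str, str]]:
        return [
            (a, b, self.by_id[a].expression_class)
            for a, b in self.pairs()
            if self.by_id[a].expression_class
        ]


_EXPECTED = {
    "chickpea": dict(n=22, non_canonical=6, clusters=1, chroms=8),
    "soybean": dict(n=63, non_canonical=13, clusters=8, chroms=16),
}


def load_paper_catalog(species: str) -> PaperCatalog:
    """Load and integrity-check the packaged catalog for one species."""
    if species not in _EXPECTED:
        raise ValueError(f"unknown species {species!r}")
    path = importlib.resources.files("auxiaa.data") / f"catalog_{species}.tsv"
    records = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        for line in handle:
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            records.append(CatalogRecord(**{k: vals.get(k, "") for k in (
                "gene_id", "chromosome", "cluster_id", "canonical_status",
                "mode", "pair_partner", "expression_class")}))
    cat = PaperCatalog(species=species, records=records)
    exp = _EXPECTED[species]
    n_nc = sum(r.canonical_status == "non_canonical" for r in records)
    n_chrom = len({r.chromosome for r in records})
    problems = []
    if len(records) != exp["n"]:
        problems.append(f"{len(records)} genes, expected {exp['n']}")
    if n_nc != exp["non_canonical"]:
        problems.append(f"{n_nc} non-canonical, expected {exp['non_canonical']}")
    if len(cat.clusters()) != exp["clusters"]:
        problems.append(f"{len(cat.clusters())} clusters, expected {exp['clusters']}")
    if n_chrom != exp["chroms"]:
        problems.append(f"{n_chrom} chromosomes, expected {exp['chroms']}")
    by_id = cat.by_id
    for r in records:
        if r.pair_partner:
            partner = by_id.get(r.pair_partner)
            if partner is None or partner.pair_partner != r.gene_id:
                problems.append(f"asymmetric pairing for {r.gene_id}")
    if problems:
        raise CatalogError(f"catalog {species}: " + "; ".join(problems))
    return cat


# ---------------------------------------------------------------------------
# Config


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic build; the seed fixes outputs exactly."""

    seed: int = 0
    species: str = "soybean"
    n_samples: int | None = None  # default: 19 soybean / 17 chickpea tissues
    protein_len_range: tuple[int, int] = (170, 250)
    decoy_len_range: tuple[int, int] = (120, 200)
    intergenic_gap: int = 2_500
    intron_len_range: tuple[int, int] = (150, 300)
    n_exons: int = 3
    te_offset: int = 2_500
    te_length: int = 500
    omega: float = 0.2
    branch_ds_range: tuple[float, float] = (0.05, 0.2)
    rho_high: float = 0.95
    rho_low: float = 0.2
    dispersion_shape: float = 50.0
    log2_rpkm_range: tuple[float, float] = (4.0, 9.0)
    tissue_effect_sd: float = 2.5
    library_size_range: tuple[float, float] = (1.5e7, 2.5e7)
    extra_element_fraction: float = 0.6

    @property
    def samples(self) -> int:
        if self.n_samples is not None:
            return self.n_samples
        return 19 if self.species == "soybean" else 17


# ---------------------------------------------------------------------------
# Codon-pair evolution


def _random_cds(protein: str, rng) -> str:
    return "".join(rng.choice(_CODONS_FOR[a]) for a in protein)


def _evolve_branch(cds: str, ds_branch: float, omega: float, rng) -> str:
    """Apply substitutions until the synonymous event count per synonymous
    site reaches ``ds_branch``; nonsynonymous proposals are accepted with
    relative probability ``omega``; stop codons are never created."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    S = sum(dup.ng_site_counts(c)[0] for c in codons)
    target = int(round(ds_branch * S))
    syn_done = 0
    cap = 200 * max(target, 1) + 2000
    it = 0
    while syn_done < target:
        it += 1
        if it > cap:
            raise RuntimeError(
                f"codon evolution: synonymous target {target} unreachable"
            )
        ci = int(rng.integers(len(codons)))
        pos = int(rng.integers(3))
        base = BASES[int(rng.integers(4))]
        old = codons[ci]
        if base == old[pos]:
            continue
        new = old[:pos] + base + old[pos + 1 :]
        if new in STOP_CODONS:
            continue
        if CODON_TO_AA[new] == CODON_TO_AA[old]:
            codons[ci] = new
            syn_done += 1
        elif rng.random() < omega:
            codons[ci] = new
    return "".join(codons)


def evolve_codon_pair(
    ancestor_cds: str, dS_target: float, omega: float, seed: int
) -> tuple[str, str]:
    """Evolve two descendant CDSs independently from a common ancestor to a
    target pairwise synonymous divergence (each branch receives half)."""
    if len(ancestor_cds) % 3:
        raise ValueError("ancestor CDS length must be a multiple of 3")
    if not (0 <= dS_target < 0.75):
        raise ValueError("dS_target must be in [0, 0.75)")
    codons = [ancestor_cds[i : i + 3] for i in range(0, len(ancestor_cds), 3)]
    bad = [c for c in codons if c not in SENSE_CODONS]
    if bad:
        raise ValueError(f"ancestor contains non-sense codons: {bad[:3]}")
    rng = np.random.default_rng(seed)
    a = _evolve_branch(ancestor_cds, dS_target / 2.0, omega, rng)
    b = _evolve_branch(ancestor_cds, dS_target / 2.0, omega, rng)
    return a, b


# ---------------------------------------------------------------------------
# Protein construction


def _motif_instances(rng) -> dict[str, str]:
    """Concrete residue strings matching the packaged motif patterns."""
    return {
        "I": "L" + rng.choice(list(AA_LETTERS)) + "L"
        + rng.choice(list(AA_LETTERS)) + "L" + rng.choice(list(AA_LETTERS)),
        "II": "GWPP" + rng.choice(["V", "I"]),
        "III": "VKV" + rng.choice(["S", "N"]) + "MDGAPYLRK",
        "IV": "GDVPWEMF" + rng.choice(["V", "I"]),
    }


_MOTIF_ORDER = ("I", "II", "III", "IV")


def _build_ancestor_protein(length: int, rng):
    """Random background with all four motif instances planted in order;
    returns (protein, motif_positions) with 0-based positions."""
    instances = _motif_instances(rng)
    total_motif = sum(len(instances[m]) for m in _MOTIF_ORDER)
    free = length - total_motif
    if free < 8:
        raise ValueError("protein too short for the motif blocks")
    # split free residues into 5 segments (before/ between/ after motifs)
    cuts = np.sort(rng.integers(0, free + 1, size=4))
    seglens = np.diff(np.concatenate([[0], cuts, [free]]))
    parts = []
    positions = {}
    cursor = 0
    for k, m in enumerate(_MOTIF_ORDER):
        seg = "".join(rng.choice(list(AA_LETTERS), size=int(seglens[k])))
        parts.append(seg)
        cursor += len(seg)
        positions[m] = cursor
        parts.append(instances[m])
        cursor += len(instances[m])
    parts.append("".join(rng.choice(list(AA_LETTERS), size=int(seglens[4]))))
    return "".join(parts), positions, instances


_MOTIF_KO = "GASPA"  # motif II knockout; matches none of the motif patterns


def _translate(cds: str) -> str:
    return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))


def _set_residues(cds: str, start: int, residues: str, rng) -> str:
    """Force a residue range, keeping codons synonymous where possible."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for k, aa in enumerate(residues):
        i = start + k
        if CODON_TO_AA[codons[i]] != aa:
            codons[i] = rng.choice(_CODONS_FOR[aa])
    return "".join(codons)


def _enforce_motifs(cds: str, positions, instances, canonical: bool, rng,
                    models) -> str:
    """Re-plant motif blocks destroyed by evolution, knock out / scrub
    motif II per canonical status, and verify the final calls."""
    for m in _MOTIF_ORDER:
        if m == "II":
            target = instances["II"] if canonical else _MOTIF_KO
        else:
            target = instances[m]
        cds = _set_residues(cds, positions[m], target, rng)
    for _ in range(20):
        prot = _translate(cds)
        res = family_scan.scan_motifs(SeqRecord("x", prot), models)
        if canonical:
            if res.hits["II"]:
                break
            raise AssertionError("planted degron not detected")
        spurious = res.hits["II"]
        if not spurious:
            break
        # chance GWPP[VI] in background: break it with a benign substitution
        pos0 = spurious[0] - 1
        cds = _set_residues(cds, pos0, "A", rng)
    else:
        raise AssertionError("could not scrub spurious degron matches")
    return cds


# ---------------------------------------------------------------------------
# The coherent build


@dataclass
class SyntheticDataset:
    config: SimConfig
    catalog: PaperCatalog
    proteome: list[SeqRecord]
    cds: dict[str, str]
    genome: dict[str, str]
    gene_models: dict[str, GeneModel]
    te_annotations: list[TeAnnotation]
    anchors: list[AnchorPair]
    counts: pd.DataFrame
    gene_lengths: pd.Series
    library_sizes: pd.Series
    planting_manifest: list[tuple[str, str, int, str]]  # gene, element, pos, strand
    decoy_ids: list[str] = field(default_factory=list)
    stress_counts: pd.DataFrame | None = None
    stress_de_genes: list[str] = field(default_factory=list)

    def gene_catalog(self) -> GeneCatalog:
        return GeneCatalog(
            genes=dict(self.gene_models),
            family_ids=set(self.catalog.gene_ids),
        )


def _components(catalog: PaperCatalog):
    """Connected components of the pair + tandem-adjacency graph; genes in
    one component derive from one ancestral coding sequence."""
    parent = {g: g for g in catalog.gene_ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for a, b in catalog.pairs():
        union(a, b)
    for members in catalog.clusters().values():
        for a, b in zip(members, members[1:]):
            union(a, b)
    comps: dict[str, list[str]] = {}
    for g in catalog.gene_ids:
        comps.setdefault(find(g), []).append(g)
    return [sorted(v, key=lambda g: catalog.gene_ids.index(g)) for k, v in
            sorted(comps.items())]


def simulate_dataset(config: SimConfig, catalog: PaperCatalog | None = None,
                     self_check: bool = True) -> SyntheticDataset:
    """Build the full, mutually consistent fixture set for one species."""
    if catalog is None:
        catalog = load_paper_catalog(config.species)
    models = family_scan.default_motif_models()
    by_id = catalog.by_id

    # --- coding sequences -------------------------------------------------
    rng_prot = np.random.default_rng([config.seed, 1])
    cds: dict[str, str] = {}
    for comp in _components(catalog):
        length = int(rng_prot.integers(*config.protein_len_range))
        anc_prot, positions, instances = _build_ancestor_protein(length, rng_prot)
        anc_cds = _random_cds(anc_prot, rng_prot)
        for gid in comp:
            ds = float(rng_prot.uniform(*config.branch_ds_range))
            evolved = (
                anc_cds if len(comp) == 1
                else _evolve_branch(anc_cds, ds, config.omega, rng_prot)
            )
            canonical = by_id[gid].canonical_status == "canonical"
            cds[gid] = _enforce_motifs(
                evolved, positions, instances, canonical, rng_prot, models
            )

    # --- decoy proteins ---------------------------------------------------
    prefix = "Ca" if config.species == "chickpea" else "Gm"
    decoy_counter = [0]

    def new_decoy() -> str:
        decoy_counter[0] += 1
        gid = f"{prefix}DEC{decoy_counter[0]:03d}"
        while True:
            length = int(rng_prot.integers(*config.decoy_len_range))
            prot = "".join(rng_prot.choice(list(AA_LETTERS), size=length))
            if decoy_counter[0] % 3 == 0:  # some decoys carry one motif
                inst = _motif_instances(rng_prot)
                m = ("I", "III", "IV")[decoy_counter[0] % 3 - 1]
                at = int(rng_prot.integers(0, length - len(inst[m])))
                prot = prot[:at] + inst[m] + prot[at + len(inst[m]):]
            res = family_scan.scan_motifs(SeqRecord(gid, prot), models)
            if not family_scan.membership_rule_default(res.hits):
                break
        cds[gid] = _random_cds(prot, rng_prot)
        return gid

    # --- chromosome layout ------------------------------------------------
    rng_geo = np.random.default_rng([config.seed, 2])
    chrom_order: dict[str, list[str]] = {}
    flank: dict[str, dict[str, str]] = {}  # family gene -> L1/L2/R1/R2 decoys
    fam_by_chrom: dict[str, list[str]] = {}
    for r in catalog.records:
        fam_by_chrom.setdefault(r.chromosome, []).append(r.gene_id)
    all_chroms = sorted(fam_by_chrom, key=lambda c: (len(c), c))
    if config.species == "soybean":
        all_chroms = [f"chr{i}" for i in range(1, 21)]
    for chrom in all_chroms:
        placement: list[str] = []
        fam = fam_by_chrom.get(chrom, [])
        groups: list[list[str]] = []
        for gid in fam:
            cid = by_id[gid].cluster_id
            if groups and cid and by_id[groups[-1][-1]].cluster_id == cid:
                groups[-1].append(gid)
            else:
                groups.append([gid])
        for group in groups:
            lefts = {}
            for gid in group:
                lefts[gid] = (new_decoy(), new_decoy())
                placement.extend(lefts[gid])
            placement.extend(group)
            for gid in group:
                rights = (new_decoy(), new_decoy())
                placement.extend(rights)
                flank[gid] = {
                    "L1": lefts[gid][0], "L2": lefts[gid][1],
                    "R1": rights[0], "R2": rights[1],
                }
        if not fam:  # decoy-only chromosome
            placement.extend(new_decoy() for _ in range(7))
        chrom_order[chrom] = placement

    # --- gene models and genome sequence ----------------------------------
    rng_seq = np.random.default_rng([config.seed, 3])
    family_ids = set(catalog.gene_ids)
    gene_models: dict[str, GeneModel] = {}
    genome: dict[str, str] = {}
    te_annotations: list[TeAnnotation] = []
    planting: list[tuple[str, str, int, str]] = []
    elements = promoter.default_element_library()
    el_by_id = {e.element_id: e for e in elements}

    def expand_iupac(pattern: str) -> str:
        return "".join(rng_seq.choice(list(promoter.IUPAC[c])) for c in pattern)

    for chrom, placement in chrom_order.items():
        pos = 2000
        chrom_genes = []
        for gid in placement:
            cds_len = len(cds[gid])
            n_exons = config.n_exons if gid in family_ids else int(
                rng_seq.integers(1, config.n_exons + 1)
            )
            splits = (
                np.sort(rng_seq.choice(
                    np.arange(30, cds_len - 30, 3), size=n_exons - 1,
                    replace=False))
                if n_exons > 1 else np.array([], dtype=int)
            )
            exon_lens = np.diff(np.concatenate([[0], splits, [cds_len]]))
            strand = "+" if rng_seq.random() < 0.5 else "-"
            exons = []
            cursor = pos
            for k, el in enumerate(exon_lens):
                exons.append((cursor, cursor + int(el) - 1))
                cursor += int(el)
                if k < len(exon_lens) - 1:
                    cursor += int(rng_seq.integers(*config.intron_len_range))
            start, end = exons[0][0], exons[-1][1]
            gene_models[gid] = GeneModel(
                gene_id=gid, chromosome=chrom, start=start, end=end,
                strand=strand, exons=exons,
                cds_start=start if strand == "+" else end,
            )
            chrom_genes.append(gid)
            pos = end + config.intergenic_gap
        chrom_len = pos + 2000
        seq = rng_seq.choice(list(BASES), size=chrom_len)
        for gid in chrom_genes:
            g = gene_models[gid]
            coding = cds[gid]
            if g.strand == "-":
                coding = promoter.revcomp(coding)
            # fill exons left-to-right with the (strand-adjusted) coding seq
            off = 0
            for (s, e) in g.exons:
                seq[s - 1 : e] = list(coding[off : off + (e - s + 1)])
                off += e - s + 1
            if gid in family_ids:
                prom, plants = _build_promoter(gid, by_id[gid], el_by_id,
                                               expand_iupac, rng_seq, config)
                planting.extend(plants)
                if g.strand == "+":
                    seq[g.cds_start - 1001 : g.cds_start - 1] = list(prom)
                else:
                    seq[g.cds_start : g.cds_start + 1000] = list(
                        promoter.revcomp(prom)
                    )
        genome[chrom] = "".join(seq)
        # transposable elements flanking transposed-labeled genes
        for gid in chrom_genes:
            if gid in family_ids and by_id[gid].mode == "transposed":
                g = gene_models[gid]
                te_annotations.append(TeAnnotation(
                    chrom, g.start - config.te_offset - config.te_length,
                    g.start - config.te_offset, f"TE_{gid}_up"))
                te_annotations.append(TeAnnotation(
                    chrom, g.end + config.te_offset,
                    g.end + config.te_offset + config.te_length,
                    f"TE_{gid}_down"))

    # --- anchors ----------------------------------------------------------
    anchors = _make_anchors(catalog, gene_models, flank, chrom_order)

    # --- proteome ---------------------------------------------------------
    proteome = [SeqRecord(gid, _translate(cds[gid])) for gid in
                sorted(cds, key=lambda g: (g not in family_ids, g))]

    # --- expression -------------------------------------------------------
    counts, lengths, libsizes = _simulate_counts(config, catalog, gene_models)
    stress, de_genes = _simulate_stress(config, catalog)

    ds = SyntheticDataset(
        config=config, catalog=catalog, proteome=proteome, cds=cds,
        genome=genome, gene_models=gene_models,
        te_annotations=te_annotations, anchors=anchors, counts=counts,
        gene_lengths=lengths, library_sizes=libsizes,
        planting_manifest=planting,
        decoy_ids=[g for g in cds if g not in family_ids],
        stress_counts=stress, stress_de_genes=de_genes,
    )
    if self_check:
        _self_check(ds)
    return ds


def _build_promoter(gid, record, el_by_id, expand_iupac, rng, config):
    """1-kb promoter (5'->3' of the gene) with planted elements."""
    prom = list(rng.choice(list(BASES), size=1000))
    plants = []
    slots = [150, 450, 750]
    chosen = [("S000270", slots[0])]  # AuxRE in every family promoter
    if rng.random() < config.extra_element_fraction:
        extra = sorted(set(el_by_id) - {"S000270"})[
            int(rng.integers(len(el_by_id) - 1))
        ]
        chosen.append((extra, slots[1 + int(rng.integers(2))]))
    for element_id, base_slot in chosen:
        el = el_by_id[element_id]
        inst = expand_iupac(el.pattern)
        pos = base_slot + int(rng.integers(0, 100))  # 1-based promoter pos
        strand = "+" if rng.random() < 0.5 else "-"
        written = inst if strand == "+" else promoter.revcomp(inst)
        prom[pos - 1 : pos - 1 + len(written)] = list(written)
        plants.append((gid, element_id, pos, strand))
    return "".join(prom), plants


def _make_anchors(catalog, gene_models, flank, chrom_order):
    """Anchor chains embedding every WGD-labeled gene in a collinear block.

    WGD pairs whose members are both WGD-labeled share a 5-anchor block
    (family pair + dedicated flanking decoys); a WGD gene left without a
    partner is anchored against a decoy-only region.  When several blocks
    share a chromosome pair and the catalog pairing runs antiparallel,
    blocks are emitted in inverted orientation so chains stay monotone.
    """
    by_id = catalog.by_id
    order_index = {}
    for chrom, placement in chrom_order.items():
        for i, gid in enumerate(placement):
            order_index[gid] = i

    def chrom_of(g):
        return gene_models[g].chromosome

    wgd = {g for g in catalog.gene_ids if by_id[g].mode == "wgd_segmental"}
    pair_blocks = []
    covered = set()
    for a, b in catalog.pairs():
        if a in wgd and b in wgd:
            pair_blocks.append((a, b))
            covered.update((a, b))
    orphan = sorted(wgd - covered)

    groups: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for a, b in pair_blocks:
        ca, cb = chrom_of(a), chrom_of(b)
        if (cb, ca) in groups:
            a, b, ca, cb = b, a, cb, ca
        groups.setdefault((ca, cb), []).append((a, b))

    anchors = []

    def emit(a, b, inverted: bool):
        fa, fb = flank[a], flank[b]
        left_a = [fa["L1"], fa["L2"]]
        right_a = [fa["R1"], fa["R2"]]
        if inverted:
            partners = [fb["R2"], fb["R1"], b, fb["L2"], fb["L1"]]
        else:
            partners = [fb["L1"], fb["L2"], b, fb["R1"], fb["R2"]]
        for ga, gb in zip(left_a + [a] + right_a, partners):
            anchors.append(AnchorPair(
                gene_a=ga, gene_b=gb,
                chrom_a=chrom_of(ga), chrom_b=chrom_of(gb),
                order_a=order_index[ga], order_b=order_index[gb],
            ))

    for (ca, cb), blocks in sorted(groups.items()):
        blocks = sorted(blocks, key=lambda p: order_index[p[0]])
        inverted = False
        if len(blocks) > 1:
            b_orders = [order_index[p[1]] for p in blocks]
            inverted = b_orders != sorted(b_orders)
        for a, b in blocks:
            emit(a, b, inverted)

    # orphans: anchor against a dedicated decoy run
    decoy_runs = []
    fam_chroms = {chrom_of(g) for g in catalog.gene_ids}
    for chrom in sorted(set(chrom_order) - fam_chroms):
        decoy_runs.append((chrom, chrom_order[chrom]))
    run_idx = 0
    used = 0
    for g in orphan:
        if not decoy_runs:
            raise CatalogError("no decoy chromosome available for orphan block")
        chrom, run = decoy_runs[run_idx % len(decoy_runs)]
        partners = run[used : used + 5]
        if len(partners) < 5:
            run_idx += 1
            used = 0
            chrom, run = decoy_runs[run_idx % len(decoy_runs)]
            partners = run[:5]
            used = 5
        else:
            used += 5
        fa = flank[g]
        for ga, gb in zip([fa["L1"], fa["L2"], g, fa["R1"], fa["R2"]], partners):
            anchors.append(AnchorPair(
                gene_a=ga, gene_b=gb,
                chrom_a=chrom_of(ga), chrom_b=chrom,
                order_a=order_index[ga], order_b=order_index[gb],
            ))
    return anchors


def _simulate_counts(config: SimConfig, catalog: PaperCatalog, gene_models):
    """Gamma-Poisson counts with latent tissue profiles; catalog pairs share
    profiles at rho_high (conserved) or rho_low (diverged)."""
    rng = np.random.default_rng([config.seed, 4])
    genes = catalog.gene_ids
    n = len(genes)
    m = config.samples
    z = np.empty((n, m))
    base = rng.uniform(*config.log2_rpkm_range, size=n)
    done = set()
    gi = {g: i for i, g in enumerate(genes)}
    for a, b, cls in catalog.expression_pairs():
        rho = config.rho_high if cls == "conserved" else config.rho_low
        za = rng.normal(0.0, 1.0, size=m)
        eps = rng.normal(0.0, 1.0, size=m)
        zb = rho * za + math.sqrt(1.0 - rho * rho) * eps
        z[gi[a]] = za * config.tissue_effect_sd
        z[gi[b]] = zb * config.tissue_effect_sd
        done.update((a, b))
    for g in genes:
        if g not in done:
            z[gi[g]] = rng.normal(0.0, config.tissue_effect_sd, size=m)
    log2_rpkm = base[:, None] + z
    lengths = pd.Series(
        {g: sum(e - s + 1 for s, e in gene_models[g].exons) for g in genes}
    )
    libsizes = pd.Series(
        rng.uniform(*config.library_size_range, size=m),
        index=[f"T{j+1:02d}" for j in range(m)],
    ).round()
    mean_rpkm = np.power(2.0, log2_rpkm)
    mean_counts = (
        mean_rpkm * lengths.values[:, None] * libsizes.values[None, :] / 1e9
    )
    shape = config.dispersion_shape
    lam = mean_counts * rng.gamma(shape, 1.0 / shape, size=mean_counts.shape)
    counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=genes, columns=libsizes.index)
    return df, lengths, libsizes


def _simulate_stress(config: SimConfig, catalog: PaperCatalog):
    """Control vs stress replicate counts (3+3): every other family gene
    responds with a 4-fold change (up or down), the rest are null."""
    rng = np.random.default_rng([config.seed, 5])
    genes = catalog.gene_ids
    shape = config.dispersion_shape
    rows = []
    de_genes = []
    for k, g in enumerate(genes):
        base = float(rng.uniform(50, 500))
        fold = 1.0
        if k % 2 == 0:
            fold = 4.0 if k % 4 == 0 else 0.25
            de_genes.append(g)
        mu = [base] * 3 + [base * fold] * 3
        lam = np.array(mu) * rng.gamma(shape, 1.0 / shape, size=6)
        rows.append(rng.poisson(lam))
    df = pd.DataFrame(
        rows, index=genes, columns=["C1", "C2", "C3", "S1", "S2", "S3"]
    )
    return df, de_genes


def _self_check(ds: SyntheticDataset) -> None:
    """Construction-time guarantees: the pipeline operators recover every
    catalog label from the built fixtures."""
    cat = ds.catalog
    gcat = ds.gene_catalog()
    clusters = genome_org.detect_tandem_clusters(gcat)
    blocks = dup.detect_collinear_blocks(ds.anchors)
    te_flags = {
        g: dup.flanking_te_test(gcat.genes[g], ds.te_annotations)[0]
        for g in cat.gene_ids
    }
    calls = dup.classify_all(set(cat.gene_ids), blocks, clusters, te_flags)
    mismatches = [
        (g, calls[g].mode, cat.by_id[g].mode)
        for g in cat.gene_ids
        if calls[g].mode != cat.by_id[g].mode
    ]
    if mismatches:
        raise AssertionError(f"mode labels not reproduced: {mismatches[:5]}")
    built_clusters = {tuple(c.member_ids) for c in clusters}
    want_clusters = {tuple(v) for v in cat.clusters().values()}
    if built_clusters != want_clusters:
        raise AssertionError(
            f"cluster mismatch: built {built_clusters} want {want_clusters}"
        )


# ---------------------------------------------------------------------------
# Spec-level generator entry points


def simulate_proteome(config: SimConfig, catalog: PaperCatalog | None = None):
    """Proteome FASTA records (family + decoys) for the catalog."""
    return simulate_dataset(config, catalog).proteome


def simulate_genome(config: SimConfig, catalog: PaperCatalog | None = None):
    """Genome dict, gene models, TE annotations and anchor pairs."""
    ds = simulate_dataset(config, catalog)
    return ds.genome, ds.gene_models, ds.te_annotations, ds.anchors


def simulate_expression(config: SimConfig, catalog: PaperCatalog | None = None):
    """Counts DataFrame, gene lengths (bp) and library sizes."""
    ds = simulate_dataset(config, catalog, self_check=False)
    return ds.counts, ds.gene_lengths, ds.library_sizes


# ---------------------------------------------------------------------------
# On-disk dataset


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Emit the dataset as the pipeline's plain-text input files."""
    import pathlib

    import yaml

    from . import formats

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    formats.write_fasta(ds.proteome, out / "proteome.fa")
    formats.write_fasta(
        [SeqRecord(g, s) for g, s in sorted(ds.cds.items())], out / "cds.fa"
    )
    formats.write_fasta(
        [SeqRecord(c, s) for c, s in sorted(ds.genome.items())], out / "genome.fa"
    )
    _write_gff3(ds, out / "genes.gff3")
    formats.write_bed(ds.te_annotations, out / "te.bed")
    with open(out / "anchors.tsv", "w") as f:
        f.write("gene_a\tgene_b\tchrom_a\tchrom_b\torder_a\torder_b\n")
        for a in ds.anchors:
            f.write(f"{a.gene_a}\t{a.gene_b}\t{a.chrom_a}\t{a.chrom_b}"
                    f"\t{a.order_a}\t{a.order_b}\n")
    ds.counts.to_csv(out / "counts.tsv", sep="\t")
    ds.library_sizes.to_frame("library_size").to_csv(
        out / "library_sizes.tsv", sep="\t"
    )
    if ds.stress_counts is not None:
        ds.stress_counts.to_csv(out / "stress_counts.tsv", sep="\t")
    with open(out / "family_ids.txt", "w") as f:
        for g in ds.catalog.gene_ids:
            f.write(g + "\n")
    src = importlib.resources.files("auxiaa.data")
    (out / "elements.tsv").write_text((src / "elements.tsv").read_text())
    (out / "catalog.tsv").write_text(
        (src / f"catalog_{ds.config.species}.tsv").read_text()
    )
    with open(out / "manifest_planting.tsv", "w") as f:
        f.write("gene_id\telement_id\tposition\tstrand\n")
        for g, e, p, s in ds.planting_manifest:
            f.write(f"{g}\t{e}\t{p}\t{s}\n")
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in ds.config.__dict__.items()}
    with open(out / "config.yaml", "w") as f:
        yaml.safe_dump(cfg, f)


def _write_gff3(ds: SyntheticDataset, path) -> None:
    with open(path, "w") as f:
        f.write("##gff-version 3\n")
        for chrom in ds.genome:
            f.write(f"##sequence-region {chrom} 1 {len(ds.genome[chrom])}\n")
        for gid in sorted(
            ds.gene_models,
            key=lambda g: (ds.gene_models[g].chromosome, ds.gene_models[g].start),
        ):
            g = ds.gene_models[gid]
            base = f"{g.chromosome}\tauxiaa_sim"
            f.write(f"{base}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={gid};Name={gid}\n")
            mid = f"{gid}.t1"
            f.write(f"{base}\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={mid};Parent={gid}\n")
            exons = g.exons if g.strand == "+" else list(reversed(g.exons))
            phase = 0
            for k, (s, e) in enumerate(g.exons, start=1):
                f.write(f"{base}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={mid}.exon{k};Parent={mid}\n")
            for k, (s, e) in enumerate(exons, start=1):
                f.write(f"{base}\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                        f"ID={mid}.cds;Parent={mid}\n")
                phase = (3 - ((e - s + 1) - phase) % 3) % 3
        f.flush()
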