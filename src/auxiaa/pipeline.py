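"""End-to-end survey pipeline: identify -> organize -> phylo -> dup ->
promoter -> expr -> report.

Each stage is independently runnable given the upstream inputs; stage
outputs are plain TSV/FASTA/Newick files under the output directory.  The
summary collects the headline numbers of the survey: family size,
canonical/non-canonical counts, chromosome distribution, tandem clusters,
duplication-mode counts with the WGD/segmental percentage, the Ka/Ks /
divergence-time / WGD-era table, promoter element presence, DE calls and
paralog expression divergence.
"""

from __future__ import annotations

import json
import logging
import pathlib
import time
from dataclasses import dataclass

import pandas as pd
import yaml

from . import duplication as dup
from . import expression as expr_mod
from . import family_scan, formats, genome_org
from . import phylogeny as phylo_mod
from . import promoter as prom_mod

log = logging.getLogger("auxiaa")


@dataclass
class PipelineConfig:
    """Input paths and every tunable parameter of the survey."""

    proteome: str = "proteome.fa"
    gff3: str = "genes.gff3"
    genome: str = "genome.fa"
    cds: str = "cds.fa"
    te_bed: str = "te.bed"
    anchors: str = "anchors.tsv"
    elements: str = ""  # empty -> packaged library
    counts: str = "counts.tsv"
    library_sizes: str = "library_sizes.tsv"
    stress_counts: str = ""  # optional: control/treatment replicate counts
    outdir: str = "results"

    motif_models: str = ""  # empty -> packaged motif patterns
    membership_min_motifs: int = 2
    gap_open: float = -10.0
    gap_extend: float = -1.0
    bootstrap_replicates: int = 1000
    bootstrap_seed: int = 0
    tandem_max_intervening: int = 1
    tandem_max_gap: int = 100_000
    min_anchors: int = 5
    max_index_gap: int = 25
    te_window: int = 10_000
    clock_rate: float = 6.1e-9
    glycine_max_ks: float = 0.3
    gamma_min_ks: float = 1.3
    promoter_length: int = 1000
    fold_threshold: float = 2.0
    de_alpha: float = 0.05
    r_threshold: float = 0.8

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def dating_params(self) -> dup.DatingParams:
        return dup.DatingParams(
            rate=self.clock_rate,
            glycine_max_ks=self.glycine_max_ks,
            gamma_min_ks=self.gamma_min_ks,
        )


class PipelineError(RuntimeError):
    pass


def _out(cfg, stage) -> pathlib.Path:
    p = pathlib.Path(cfg.outdir) / stage
    p.mkdir(parents=True, exist_ok=True)
    return p


def preflight(cfg: PipelineConfig) -> None:
    """Fail before any stage runs if a required input is missing."""
    required = ["proteome", "gff3", "genome", "cds", "te_bed", "anchors",
                "counts", "library_sizes"]
    missing = [
        f"{name}={getattr(cfg, name)}"
        for name in required
        if getattr(cfg, name) and not pathlib.Path(getattr(cfg, name)).exists()
    ]
    if missing:
        raise PipelineError("missing input file(s): " + ", ".join(missing))


# ---------------------------------------------------------------------------
# Stages


def _motif_models(cfg):
    if cfg.motif_models:
        return family_scan.load_motif_models(cfg.motif_models)
    return family_scan.default_motif_models()


def _membership_rule(cfg):
    def rule(hits):
        return sum(bool(hits.get(m)) for m in ("II", "III", "IV")) >= (
            cfg.membership_min_motifs
        )

    return rule


def stage_identify(cfg: PipelineConfig):
    proteins = formats.read_fasta(cfg.proteome)
    results = family_scan.call_family(
        proteins, _motif_models(cfg), _membership_rule(cfg)
    )
    by_id = {p.id: p for p in proteins}
    rows = []
    for r in results:
        if not r.is_family_member:
            continue
        prof = family_scan.physicochemical_profile(by_id[r.protein_id])
        rows.append({
            "gene_id": r.protein_id,
            "length": prof.length,
            "molecular_weight": round(prof.molecular_weight, 2),
            "pI": round(prof.isoelectric_point, 2),
            "canonical_status": r.canonical_status,
        })
    table = pd.DataFrame(rows).set_index("gene_id").sort_index()
    out = _out(cfg, "identify")
    table.to_csv(out / "members.tsv", sep="\t")
    return table


def _load_members(cfg) -> pd.DataFrame:
    path = pathlib.Path(cfg.outdir) / "identify" / "members.tsv"
    if path.exists():
        return pd.read_csv(path, sep="\t", index_col=0)
    return stage_identify(cfg)


def _load_catalog(cfg) -> formats.GeneCatalog:
    members = _load_members(cfg)
    return formats.read_gff3(cfg.gff3, family_ids=set(members.index))


def stage_organize(cfg: PipelineConfig):
    catalog = _load_catalog(cfg)
    counts, absent = genome_org.chromosome_distribution(catalog)
    clusters = genome_org.detect_tandem_clusters(
        catalog, cfg.tandem_max_intervening, cfg.tandem_max_gap
    )
    out = _out(cfg, "organize")
    pd.DataFrame(
        [{"chromosome": c, "family_genes": n} for c, n in counts.items()]
    ).to_csv(out / "distribution.tsv", sep="\t", index=False)
    (out / "absent_chromosomes.txt").write_text("\n".join(absent) + "\n")
    with open(out / "clusters.tsv", "w") as f:
        f.write("chromosome\tmembers\tstart\tend\n")
        for c in clusters:
            f.write(f"{c.chromosome}\t{','.join(c.member_ids)}"
                    f"\t{c.span[0]}\t{c.span[1]}\n")
    rows = []
    for g in catalog.family_genes():
        introns, n = genome_org.intron_structure(g)
        rows.append({"gene_id": g.gene_id, "exons": len(g.exons), "introns": n,
                     "intron_bp": sum(e - s + 1 for s, e in introns)})
    pd.DataFrame(rows).set_index("gene_id").to_csv(out / "introns.tsv", sep="\t")
    return catalog, counts, absent, clusters


def _family_proteins(cfg):
    members = _load_members(cfg)
    proteins = formats.read_fasta(cfg.proteome)
    return [p for p in proteins if p.id in set(members.index)]


def stage_phylo(cfg: PipelineConfig):
    proteins = sorted(_family_proteins(cfg), key=lambda p: p.id)
    matrix = None  # BLOSUM62
    alignments = []
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            alignments.append(phylo_mod.global_align(
                proteins[i], proteins[j], matrix, cfg.gap_open, cfg.gap_extend
            ))
    labels = [p.id for p in proteins]
    D = phylo_mod.distance_matrix(alignments, labels)
    tree = phylo_mod.upgma(D)
    msa = phylo_mod.progressive_msa(
        proteins, tree, matrix, cfg.gap_open, cfg.gap_extend
    )
    tree = phylo_mod.bootstrap_support(
        msa, cfg.bootstrap_replicates, cfg.bootstrap_seed, tree
    )
    pairs = phylo_mod.extract_sister_pairs(tree, species_of=lambda g: g[:2])
    out = _out(cfg, "phylo")
    (out / "tree.nwk").write_text(formats.write_newick(tree) + "\n")
    sim = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in alignments:
        sim.loc[a.id_a, a.id_b] = sim.loc[a.id_b, a.id_a] = a.percent_similarity
    for l in labels:
        sim.loc[l, l] = 100.0
    sim.to_csv(out / "similarity.tsv", sep="\t")
    with open(out / "sister_pairs.tsv", "w") as f:
        f.write("id_a\tid_b\tpair_class\n")
        for p in pairs:
            f.write(f"{p.id_a}\t{p.id_b}\t{p.pair_class}\n")
    return tree, msa, pairs, alignments


def _read_anchors(path) -> list[dup.AnchorPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        dup.AnchorPair(r.gene_a, r.gene_b, r.chrom_a, r.chrom_b,
                       int(r.order_a), int(r.order_b))
        for r in df.itertuples()
    ]


def _detect_duplications(cfg, catalog):
    clusters = genome_org.detect_tandem_clusters(
        catalog, cfg.tandem_max_intervening, cfg.tandem_max_gap
    )
    anchors = _read_anchors(cfg.anchors)
    blocks = dup.detect_collinear_blocks(anchors, cfg.min_anchors, cfg.max_index_gap)
    tes = formats.read_bed(cfg.te_bed)
    te_flags = {
        g: dup.flanking_te_test(catalog.genes[g], tes, cfg.te_window)[0]
        for g in catalog.family_ids
    }
    calls = dup.classify_all(catalog.family_ids, blocks, clusters, te_flags)
    return clusters, blocks, calls


def duplicate_pairs(cfg, catalog, clusters, blocks):
    """Family duplicate pairs: family-family anchors inside collinear
    blocks, plus consecutive members of each tandem cluster."""
    fam = catalog.family_ids
    pairs = set()
    for b in blocks:
        for a in b.anchors:
            if a.gene_a in fam and a.gene_b in fam:
                pairs.add(tuple(sorted((a.gene_a, a.gene_b))))
    for c in clusters:
        for x, y in zip(c.member_ids, c.member_ids[1:]):
            pairs.add(tuple(sorted((x, y))))
    return sorted(pairs)


def stage_dup(cfg: PipelineConfig):
    catalog = _load_catalog(cfg)
    clusters, blocks, calls = _detect_duplications(cfg, catalog)
    out = _out(cfg, "duplication")
    with open(out / "blocks.tsv", "w") as f:
        f.write("block_id\tchrom_a\tchrom_b\torientation\tn_anchors\tgenes\n")
        for b in blocks:
            f.write(f"{b.block_id}\t{b.chrom_a}\t{b.chrom_b}\t{b.orientation}"
                    f"\t{len(b.anchors)}\t{','.join(sorted(b.genes))}\n")
    modes = pd.DataFrame(
        [{"gene_id": g, "mode": c.mode} for g, c in sorted(calls.items())]
    ).set_index("gene_id")
    modes.to_csv(out / "modes.tsv", sep="\t")

    pairs = duplicate_pairs(cfg, catalog, clusters, blocks)
    proteins = {p.id: p for p in _family_proteins(cfg)}
    cds = {r.id: r.sequence for r in formats.read_fasta(cfg.cds)}
    params = cfg.dating_params()
    rows = []
    for a, b in pairs:
        aln = phylo_mod.global_align(
            proteins[a], proteins[b], None, cfg.gap_open, cfg.gap_extend
        )
        try:
            codon_aln = dup.back_translate(
                aln.aligned_a, aln.aligned_b, cds[a], cds[b], a, b
            )
            res = dup.ng_kaks(codon_aln)
        except dup.SaturationError:
            rows.append({"gene_a": a, "gene_b": b, "saturated": True})
            continue
        rows.append({
            "gene_a": a, "gene_b": b, "saturated": False,
            "Ka": round(res.ka, 4), "Ks": round(res.ks, 4),
            "ratio": round(res.ratio, 4) if res.ratio is not None else "",
            "S": round(res.S, 1), "N": round(res.N, 1),
            "T_mya": round(dup.divergence_time(res.ks, params), 2),
            "event": dup.assign_wgd_event(res.ks, params),
        })
    kaks = pd.DataFrame(rows)
    kaks.to_csv(out / "kaks.tsv", sep="\t", index=False)
    return calls, blocks, clusters, pairs, kaks


def stage_promoter(cfg: PipelineConfig):
    catalog = _load_catalog(cfg)
    genome = {r.id: r.sequence for r in formats.read_fasta(cfg.genome)}
    library = (
        prom_mod.load_element_library(cfg.elements)
        if cfg.elements
        else prom_mod.default_element_library()
    )
    promoters = prom_mod.extract_promoters(genome, catalog, cfg.promoter_length)
    hits = []
    for p in promoters:
        hits.extend(prom_mod.scan_elements(p, library))
    out = _out(cfg, "promoter")
    formats.write_fasta(
        [formats.SeqRecord(p.gene_id, p.sequence) for p in promoters],
        out / "promoters.fa",
    )
    with open(out / "hits.tsv", "w") as f:
        f.write("gene_id\telement_id\tposition\tstrand\n")
        for h in hits:
            f.write(f"{h.gene_id}\t{h.element_id}\t{h.position}\t{h.strand}\n")
    table = prom_mod.element_presence_table(
        hits, [p.gene_id for p in promoters], library
    )
    table.to_csv(out / "presence.tsv", sep="\t")
    return promoters, hits, table


def stage_expr(cfg: PipelineConfig):
    catalog = _load_catalog(cfg)
    counts_df = formats.read_matrix(cfg.counts)
    libsizes = formats.read_matrix(cfg.library_sizes)["library_size"]
    lengths = pd.Series({
        g.gene_id: sum(e - s + 1 for s, e in g.exons)
        for g in catalog.family_genes()
    })
    counts_df = counts_df.loc[counts_df.index.intersection(lengths.index)]
    cm = expr_mod.CountMatrix(
        counts=counts_df, gene_lengths=lengths.loc[counts_df.index],
        library_sizes=libsizes,
    )
    rpkm_df = expr_mod.rpkm(cm)
    z = expr_mod.zscore_rows(rpkm_df)
    _, order = expr_mod.hclust_order(z)
    clusters, blocks, _ = _detect_duplications(cfg, catalog)
    pairs = duplicate_pairs(cfg, catalog, clusters, blocks)
    divergence = [
        expr_mod.paralog_divergence((a, b), rpkm_df, cfg.r_threshold)
        for a, b in pairs
        if a in rpkm_df.index and b in rpkm_df.index
    ]
    out = _out(cfg, "expression")
    rpkm_df.round(3).to_csv(out / "rpkm.tsv", sep="\t")
    z.round(4).to_csv(out / "zscores.tsv", sep="\t")
    (out / "cluster_order.tsv").write_text("\n".join(order) + "\n")
    with open(out / "paralog_divergence.tsv", "w") as f:
        f.write("id_a\tid_b\tpearson_r\tverdict\n")
        for d in divergence:
            r = "" if d.pearson_r is None else f"{d.pearson_r:.4f}"
            f.write(f"{d.id_a}\t{d.id_b}\t{r}\t{d.verdict}\n")
    de_results = []
    if cfg.stress_counts:
        stress = formats.read_matrix(cfg.stress_counts)
        ctrl = [c for c in stress.columns if c.lower().startswith("c")]
        treat = [c for c in stress.columns if not c.lower().startswith("c")]
        for g in stress.index:
            de_results.append(expr_mod.call_de(
                stress.loc[g, ctrl], stress.loc[g, treat], g,
                fold_threshold=cfg.fold_threshold, alpha=cfg.de_alpha,
            ))
        with open(out / "de.tsv", "w") as f:
            f.write("gene_id\tfold_change\tp_value\tis_de\n")
            for d in de_results:
                f.write(f"{d.gene_id}\t{d.fold_change:.3f}\t{d.p_value:.4g}"
                        f"\t{int(d.is_de)}\n")
    expr_mod.tissue_specificity(rpkm_df).round(4).to_csv(
        out / "tissue_specificity.tsv", sep="\t"
    )
    return rpkm_df, divergence, de_results


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and write a machine-readable summary.

    Raises :class:`PipelineError` before any stage runs if an input is
    missing; stage errors propagate.  Returns the summary dict.
    """
    preflight(cfg)
    summary: dict = {}
    log.info("parameters: %s", cfg)

    def timed(name, fn):
        t0 = time.time()
        log.info("stage %s: start", name)
        out = fn(cfg)
        log.info("stage %s: done in %.2fs", name, time.time() - t0)
        return out

    members = timed("identify", stage_identify)
    catalog, counts, absent, clusters = timed("organize", stage_organize)
    tree, msa, sisters, alignments = timed("phylo", stage_phylo)
    calls, blocks, clusters, pairs, kaks = timed("dup", stage_dup)
    promoters, hits, presence = timed("promoter", stage_promoter)
    rpkm_df, divergence, de_results = timed("expr", stage_expr)

    mode_counts: dict[str, int] = {}
    for c in calls.values():
        mode_counts[c.mode] = mode_counts.get(c.mode, 0) + 1
    n_fam = len(members)
    wgd_pct = 100.0 * mode_counts.get("wgd_segmental", 0) / n_fam if n_fam else 0.0
    verdicts = [d.verdict for d in divergence]
    summary.update({
        "family_size": n_fam,
        "canonical": int((members["canonical_status"] == "canonical").sum()),
        "non_canonical": int(
            (members["canonical_status"] == "non_canonical").sum()
        ),
        "chromosomes_with_family_genes": len(counts),
        "absent_chromosomes": absent,
        "distribution": counts,
        "n_tandem_clusters": len(clusters),
        "tandem_clusters": [c.member_ids for c in clusters],
        "mode_counts": mode_counts,
        "wgd_segmental_percent": round(wgd_pct, 2),
        "n_duplicate_pairs": len(pairs),
        "n_sister_pairs": len(sisters),
        "n_element_hits": len(hits),
        "n_de": sum(d.is_de for d in de_results),
        "divergence_conserved": verdicts.count("conserved"),
        "divergence_diverged": verdicts.count("diverged"),
    })
    outdir = pathlib.Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "summary.json", "w") as f:
        json.dump(summary, f, indent=1, default=str)
    return summary
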