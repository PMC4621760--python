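import itertools
import warnings

import numpy as np
import pytest

from auxiaa import duplication as dup
from auxiaa import synthetic_data as sd
from auxiaa.formats import GeneModel, TeAnnotation


def anchor(ga, gb, oa, ob, ca="c1", cb="c2"):
    return dup.AnchorPair(ga, gb, ca, cb, oa, ob)


class TestCollinearBlocks:
    def test_five_collinear_anchors_form_same_orientation_block(self):
        anchors = [anchor(f"a{i}", f"b{i}", i, i) for i in range(1, 6)]
        (b,) = dup.detect_collinear_blocks(anchors)
        assert b.orientation == "same"
        assert len(b.anchors) == 5

    def test_reversed_partner_order_gives_inverted_block(self):
        anchors = [anchor(f"a{i}", f"b{i}", i, 6 - i) for i in range(1, 6)]
        (b,) = dup.detect_collinear_blocks(anchors)
        assert b.orientation == "inverted"

    def test_min_anchor_threshold(self):
        anchors = [anchor(f"a{i}", f"b{i}", i, i) for i in range(1, 5)]
        assert dup.detect_collinear_blocks(anchors, min_anchors=5) == []
        assert len(dup.detect_collinear_blocks(anchors, min_anchors=4)) == 1

    def test_index_gap_cap_splits_chains(self):
        anchors = [anchor(f"a{i}", f"b{i}", i, i) for i in
                   [1, 2, 3, 4, 5, 100, 101, 102, 103, 104]]
        blocks = dup.detect_collinear_blocks(anchors, max_index_gap=25)
        assert len(blocks) == 2

    def test_each_anchor_used_once(self):
        anchors = [anchor(f"a{i}", f"b{i}", i, i) for i in range(1, 13)]
        blocks = dup.detect_collinear_blocks(anchors)
        seen = [a for b in blocks for a in b.anchors]
        assert len(seen) == len(set(seen)) == 12


class TestFlankingTe:
    gene = GeneModel("g", "chr1", 50_000, 52_000, "+")

    def test_tes_on_both_flanks(self):
        tes = [TeAnnotation("chr1", 48_500, 49_000, "u"),
               TeAnnotation("chr1", 53_000, 53_400, "d")]
        flag, nearest = dup.flanking_te_test(self.gene, tes)
        assert flag and len(nearest) == 2

    def test_one_sided_te_is_not_enough(self):
        tes = [TeAnnotation("chr1", 48_500, 49_000, "u")]
        assert dup.flanking_te_test(self.gene, tes)[0] is False

    def test_window_and_chromosome_respected(self):
        tes = [TeAnnotation("chr1", 30_000, 30_400, "far"),
               TeAnnotation("chr2", 53_000, 53_400, "wrong")]
        assert dup.flanking_te_test(self.gene, tes)[0] is False


class TestModeClassification:
    def _cluster(self, members):
        from auxiaa.genome_org import TandemCluster

        return TandemCluster("chr1", members, (1, 2))

    def test_precedence_block_over_cluster(self):
        anchors = [anchor("g1", f"x{i}", i, i) for i in range(5)]
        block = dup.CollinearBlock("B1", anchors, "c1", "c2", "same")
        call = dup.classify_duplication_mode(
            "g1", {"g1", "g2"}, [block], [self._cluster(["g1", "g2"])], {}
        )
        assert call.mode == "wgd_segmental"

    def test_cluster_member_outside_blocks_is_tandem(self):
        call = dup.classify_duplication_mode(
            "g2", {"g1", "g2"}, [], [self._cluster(["g1", "g2"])], {}
        )
        assert call.mode == "tandem"

    def test_te_flanked_singleton_is_transposed(self):
        call = dup.classify_duplication_mode(
            "g3", {"g1", "g3"}, [], [], {"g3": True}
        )
        assert call.mode == "transposed"

    def test_otherwise_dispersed(self):
        call = dup.classify_duplication_mode(
            "g3", {"g1", "g3"}, [], [], {"g3": False}
        )
        assert call.mode == "dispersed"

    def test_every_family_gene_gets_exactly_one_mode(self, soy_dataset):
        from auxiaa import genome_org

        cat = soy_dataset.gene_catalog()
        clusters = genome_org.detect_tandem_clusters(cat)
        blocks = dup.detect_collinear_blocks(soy_dataset.anchors)
        flags = {g: dup.flanking_te_test(cat.genes[g],
                                         soy_dataset.te_annotations)[0]
                 for g in cat.family_ids}
        calls = dup.classify_all(cat.family_ids, blocks, clusters, flags)
        assert set(calls) == cat.family_ids
        assert all(c.mode in {"wgd_segmental", "tandem", "transposed",
                              "dispersed"} for c in calls.values())


class TestBackTranslate:
    def test_maps_residue_columns_to_codons(self):
        aln = dup.back_translate("MA", "MA", "ATGGCT", "ATGGCA")
        assert aln.columns == [("ATG", "ATG"), ("GCT", "GCA")]

    def test_gap_residue_becomes_codon_gap(self):
        aln = dup.back_translate("M-A", "MKA", "ATGGCT", "ATGAAAGCA")
        assert aln.columns[1] == ("---", "AAA")

    @pytest.mark.parametrize(
        "pa,pb,ca,cb",
        [
            ("MA", "MA", "ATGGCTA", "ATGGCA"),  # length not 3x residues
            ("MA", "MA", "ATGTAA", "ATGGCA"),  # internal stop
            ("MA", "MA", "ATGTGT", "ATGGCA"),  # translation mismatch
        ],
    )
    def test_invalid_cds_rejected(self, pa, pb, ca, cb):
        with pytest.raises(ValueError):
            dup.back_translate(pa, pb, ca, cb)


class TestNgCounting:
    @pytest.mark.parametrize(
        "codon,s",
        [
            ("TTT", 1 / 3),  # only TTC synonymous among 9 neighbours
            ("ATG", 0.0),  # Met has no synonymous neighbour
            ("TGG", 0.0),  # Trp: stops excluded, renormalized
        ],
    )
    def test_site_counts(self, codon, s):
        got_s, got_n = dup.ng_site_counts(codon)
        assert got_s == pytest.approx(s)
        assert got_s + got_n == 3.0

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            dup.ng_site_counts("TAA")

    def test_site_sum_exact_for_all_sense_codons(self):
        for c in dup.SENSE_CODONS:
            s, n = dup.ng_site_counts(c)
            assert s + n == 3.0

    @pytest.mark.parametrize(
        "a,b,sd,nd",
        [
            ("TTT", "TTT", 0.0, 0.0),
            ("TTT", "TTC", 1.0, 0.0),  # Phe -> Phe
            ("TTT", "TTA", 0.0, 1.0),  # Phe -> Leu
            ("TTT", "TCA", 0.5, 1.5),  # two pathways averaged
        ],
    )
    def test_codon_differences(self, a, b, sd, nd):
        assert dup.ng_codon_diff(a, b) == pytest.approx((sd, nd))

    def test_pathway_average_matches_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(21)
        pairs = [tuple(rng.choice(dup.SENSE_CODONS, size=2)) for _ in range(200)]
        for a, b in pairs:
            want = brute_force_diff(a, b)
            assert dup.ng_codon_diff(a, b) == pytest.approx(want), (a, b)


def brute_force_diff(a, b):
    """Independent pathway enumerator used as the NG counting oracle."""
    diff = [p for p in range(3) if a[p] != b[p]]
    if not diff:
        return 0.0, 0.0
    open_paths, all_paths = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, blocked = a, 0, 0, False
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1:]
            if nxt in dup.STOP_CODONS:
                blocked = True
                nd += 1
            elif dup.CODON_TO_AA[nxt] == dup.CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if not blocked:
            open_paths.append((sd, nd))
    pool = open_paths or all_paths
    return (sum(s for s, _ in pool) / len(pool),
            sum(n for _, n in pool) / len(pool))


class TestNgKaks:
    def _aln(self, a, b):
        cols = list(zip([a[i:i + 3] for i in range(0, len(a), 3)],
                        [b[i:i + 3] for i in range(0, len(b), 3)]))
        return dup.CodonAlignment("a", "b", cols)

    def test_identical_sequences(self):
        res = dup.ng_kaks(self._aln("ATGGCT", "ATGGCT"))
        assert res.ka == res.ks == 0.0
        assert res.ratio is None

    def test_jukes_cantor_value(self):
        # p = 0.3 corrects to -(3/4) ln(0.6) = 0.3831
        assert dup._jukes_cantor(0.3) == pytest.approx(0.3831, abs=1e-4)

    def test_saturation_raises(self):
        with pytest.raises(dup.SaturationError):
            dup._jukes_cantor(0.8)

    def test_site_counts_sum_rule(self):
        res = dup.ng_kaks(self._aln("ATGGCTTTTAAACCCGGG", "ATGGCATTTAAACCCGGG"))
        assert res.S + res.N == pytest.approx(3 * res.n_codons)

    def test_matches_biopython_ng86_cross_check(self):
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(8)
        anc = "".join(rng.choice(dup.SENSE_CODONS, size=300))
        a, b = sd.evolve_codon_pair(anc, 0.4, 0.2, seed=3)
        res = dup.ng_kaks(self._aln(a, b))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dn, ds_ = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        # conventions for stop-adjacent codons differ slightly between
        # implementations; agreement within 10% is the sanity bound
        assert res.ka == pytest.approx(dn, rel=0.10, abs=0.01)
        assert res.ks == pytest.approx(ds_, rel=0.10, abs=0.01)

    def test_parameter_recovery_within_20_percent(self):
        rng = np.random.default_rng(9)
        for ds_target in (0.2, 0.4):
            anc = "".join(rng.choice(dup.SENSE_CODONS, size=400))
            a, b = sd.evolve_codon_pair(anc, ds_target, 0.2,
                                        seed=int(ds_target * 100))
            res = dup.ng_kaks(self._aln(a, b))
            assert res.ks == pytest.approx(ds_target, rel=0.2)
            assert res.ratio < 1.0


class TestDating:
    @pytest.mark.parametrize("ks,t", [(0.0, 0.0), (0.122, 10.0), (1.22, 100.0)])
    def test_divergence_time_closed_form(self, ks, t):
        assert dup.divergence_time(ks) == pytest.approx(t, rel=1e-12)

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            dup.divergence_time(-0.1)

    def test_linearity(self):
        assert dup.divergence_time(0.6) == pytest.approx(
            2 * dup.divergence_time(0.3))

    @pytest.mark.parametrize(
        "ks,event",
        [
            (0.25, "glycine_wgd"),
            (0.3, "legume_wgd"),  # boundaries inclusive to the legume bin
            (0.7, "legume_wgd"),
            (1.3, "legume_wgd"),
            (1.5, "gamma_wgt"),
        ],
    )
    def test_event_bins(self, ks, event):
        assert dup.assign_wgd_event(ks) == event

    def test_event_assignment_monotone_in_ks(self):
        order = {"glycine_wgd": 0, "legume_wgd": 1, "gamma_wgt": 2}
        grid = np.linspace(0, 2.5, 60)
        events = [order[dup.assign_wgd_event(k)] for k in grid]
        assert events == sorted(events)
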