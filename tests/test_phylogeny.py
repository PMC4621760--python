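import numpy as np
import pytest
from Bio.Align import substitution_matrices

from auxiaa import phylogeny as ph
from auxiaa.formats import SeqRecord

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_nw(a, b, matrix, go, ge):
    """Enumerate every global alignment; affine gap of length k costs
    go + (k-1)*ge.  Exponential — for length <= 5 only."""
    best = [-np.inf]

    def rec(i, j, prev, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + matrix[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, "X", score + (ge if prev == "X" else go))
        if j < len(b):
            rec(i, j + 1, "Y", score + (ge if prev == "Y" else go))

    rec(0, 0, "", 0.0)
    return best[0]


class TestGlobalAlign:
    def test_identical_triplet_score_and_identity(self):
        a = ph.global_align(SeqRecord("a", "AAA"), SeqRecord("b", "AAA"))
        assert a.score == 12.0  # 3 x BLOSUM62 A:A = 4
        assert a.percent_identity == 100.0

    def test_single_residues_align_without_gaps(self):
        a = ph.global_align(SeqRecord("a", "A"), SeqRecord("b", "A"))
        assert (a.aligned_a, a.aligned_b) == ("A", "A")

    def test_single_gap_column(self):
        a = ph.global_align(SeqRecord("a", "AC"), SeqRecord("b", "AGC"))
        assert len(a.aligned_a) == 3
        assert a.aligned_a.count("-") == 1

    def test_empty_sequence_rejected(self):
        rec = SeqRecord("a", "A")
        rec.sequence = ""
        with pytest.raises(ValueError):
            ph.global_align(rec, SeqRecord("b", "A"))

    def test_score_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(11)
        letters = list("ARNDCQEG")
        for _ in range(25):
            a = "".join(rng.choice(letters, size=int(rng.integers(1, 6))))
            b = "".join(rng.choice(letters, size=int(rng.integers(1, 6))))
            got = ph.global_align(SeqRecord("a", a), SeqRecord("b", b)).score
            want = brute_force_nw(a, b, BLOSUM62, -10.0, -1.0)
            assert got == pytest.approx(want), (a, b)

    def test_score_symmetry_gives_symmetric_distances(self):
        rng = np.random.default_rng(12)
        letters = list("ARNDCQEG")
        seqs = [SeqRecord(f"s{i}", "".join(rng.choice(letters, size=12)))
                for i in range(4)]
        for i in range(4):
            for j in range(i + 1, 4):
                ab = ph.global_align(seqs[i], seqs[j])
                ba = ph.global_align(seqs[j], seqs[i])
                assert ab.score == ba.score
                assert ab.percent_identity == pytest.approx(
                    ba.percent_identity)


class TestDistanceMatrix:
    def test_distance_is_one_minus_identity(self):
        a = ph.PairwiseAlignment("a", "b", "AA", "AA", 8, 100.0, 100.0)
        c = ph.PairwiseAlignment("a", "c", "AA", "AC", 4, 50.0, 50.0)
        bc = ph.PairwiseAlignment("b", "c", "AA", "AC", 4, 50.0, 50.0)
        D = ph.distance_matrix([a, c, bc])
        assert D.get("a", "b") == 0.0
        assert D.get("a", "c") == 0.5

    def test_missing_pair_rejected(self):
        a = ph.PairwiseAlignment("a", "b", "AA", "AA", 8, 100.0, 100.0)
        with pytest.raises(ValueError):
            ph.distance_matrix([a], labels=["a", "b", "c"])


def random_ultrametric_tree(rng, n):
    """Random topology with strictly increasing merge heights; returns
    (clade -> height dict, distance matrix, labels)."""
    labels = [f"T{i}" for i in range(n)]
    clusters = [{l} for l in labels]
    heights = np.sort(rng.uniform(0.05, 1.0, size=n - 1))
    clades = {}
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        merged = clusters[i] | clusters[j]
        clades[frozenset(merged)] = float(h)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            h = min(v for cl, v in clades.items()
                    if {labels[i], labels[j]} <= cl)
            D[i, j] = D[j, i] = 2 * h
    return clades, ph.DistanceMatrix(labels=labels, values=D)


class TestUpgma:
    def test_hand_worked_three_taxa(self):
        D = ph.DistanceMatrix(
            labels=["A", "B", "C"],
            values=np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0.0]]),
        )
        tree = ph.upgma(D)
        heights = {frozenset(l.label for l in n.leaves()): n.height
                   for n in tree.internal_nodes()}
        assert heights == {frozenset("AB"): 1.0, frozenset("ABC"): 3.0}

    def test_tie_break_prefers_lexicographically_first_pair(self):
        D = ph.DistanceMatrix(
            labels=["C", "A", "B"], values=np.ones((3, 3)) - np.eye(3)
        )
        tree = ph.upgma(D)
        cherries = [n for n in tree.internal_nodes()
                    if all(c.is_leaf() for c in n.children)]
        assert {c.label for c in cherries[0].children} == {"A", "B"}

    def test_two_taxa(self):
        D = ph.DistanceMatrix(labels=["A", "B"],
                              values=np.array([[0, 1.0], [1.0, 0]]))
        tree = ph.upgma(D)
        assert tree.root.height == 0.5

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            ph.upgma(ph.DistanceMatrix(labels=["A"], values=np.zeros((1, 1))))

    def test_output_is_ultrametric(self):
        rng = np.random.default_rng(13)
        M = rng.uniform(0.1, 1, size=(7, 7))
        D = ph.DistanceMatrix(labels=list("ABCDEFG"),
                              values=(M + M.T) * (1 - np.eye(7)))
        tree = ph.upgma(D)

        def check(node):
            for c in node.children:
                assert node.height >= c.height - 1e-12
                check(c)

        check(tree.root)
        assert all(l.height == 0 for l in tree.root.leaves())

    def test_recovers_generating_tree_exactly(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            clades, D = random_ultrametric_tree(rng, 8)
            tree = ph.upgma(D)
            got = {frozenset(l.label for l in n.leaves()): n.height
                   for n in tree.internal_nodes()}
            assert got.keys() == clades.keys()
            for cl in clades:
                assert got[cl] == pytest.approx(clades[cl], abs=1e-12)


class TestProgressiveMsa:
    def _seqs(self, seqs):
        return [SeqRecord(f"s{i}", s) for i, s in enumerate(seqs)]

    def _tree(self, seqs):
        alns = [ph.global_align(a, b) for i, a in enumerate(seqs)
                for b in seqs[i + 1:]]
        return ph.upgma(ph.distance_matrix(alns, [s.id for s in seqs]))

    def test_identical_sequences_align_gapless(self):
        seqs = self._seqs(["MKV", "MKV"])
        msa = ph.progressive_msa(seqs, self._tree(seqs))
        assert set(msa.values()) == {"MKV"}

    def test_extra_residue_creates_one_gap_column(self):
        seqs = self._seqs(["MKVLE", "MKVLE", "MKVALE"])
        msa = ph.progressive_msa(seqs, self._tree(seqs))
        assert len(set(map(len, msa.values()))) == 1
        assert msa["s2"].count("-") == 0
        assert msa["s0"].count("-") == 1

    def test_rows_ungap_to_inputs(self):
        rng = np.random.default_rng(15)
        letters = list("ARNDCQEGHILKMFPSTWYV")
        seqs = [SeqRecord(f"s{i}",
                          "".join(rng.choice(letters,
                                             size=int(rng.integers(10, 20)))))
                for i in range(5)]
        msa = ph.progressive_msa(seqs, self._tree(seqs))
        for s in seqs:
            assert msa[s.id].replace("-", "") == s.sequence

    def test_guide_mismatch_rejected(self):
        seqs = self._seqs(["MKV", "MKL"])
        tree = self._tree(self._seqs(["MKV", "MKL", "MKI"]))
        with pytest.raises(ValueError):
            ph.progressive_msa(seqs, tree)


class TestBootstrap:
    def test_unanimous_columns_give_full_support(self):
        msa = {"A": "AAGG", "B": "AAGG", "C": "CCTT", "D": "CCTT"}
        tree = ph.bootstrap_support(msa, n_replicates=100, seed=0)
        sup = {frozenset(l.label for l in n.leaves()): n.support
               for n in tree.internal_nodes()}
        assert sup[frozenset("AB")] == 1.0
        assert sup[frozenset("CD")] == 1.0

    def test_supports_in_unit_interval_and_seed_stability(self):
        rng = np.random.default_rng(16)
        letters = list("ARND")
        msa = {f"s{i}": "".join(rng.choice(letters, size=60))
               for i in range(6)}
        t1 = ph.bootstrap_support(dict(msa), 1000, seed=1)
        t2 = ph.bootstrap_support(dict(msa), 1000, seed=2)
        s1 = {frozenset(l.label for l in n.leaves()): n.support
              for n in t1.internal_nodes()}
        s2 = {frozenset(l.label for l in n.leaves()): n.support
              for n in t2.internal_nodes()}
        for cl, v in s1.items():
            assert 0.0 <= v <= 1.0
            assert abs(v - s2[cl]) <= 0.05  # binomial error at n=1000


class TestSisterPairs:
    def _leaf(self, l):
        return ph.TreeNode(label=l)

    def test_simple_cherry(self):
        root = ph.TreeNode(height=2, children=[
            ph.TreeNode(height=1, children=[self._leaf("A"), self._leaf("B")]),
            self._leaf("C")])
        pairs = ph.extract_sister_pairs(ph.UltrametricTree(root),
                                        species_of=lambda x: "sp")
        assert [(p.id_a, p.id_b, p.pair_class) for p in pairs] == [
            ("A", "B", "paralog")]

    def test_caterpillar_has_single_cherry(self):
        node = ph.TreeNode(height=1,
                           children=[self._leaf("A"), self._leaf("B")])
        for h, l in ((2, "C"), (3, "D")):
            node = ph.TreeNode(height=h, children=[node, self._leaf(l)])
        pairs = ph.extract_sister_pairs(ph.UltrametricTree(node),
                                        species_of=lambda x: "sp")
        assert len(pairs) == 1

    def test_cross_species_cherry_is_ortholog(self):
        root = ph.TreeNode(height=1, children=[
            self._leaf("GmIAA1"), self._leaf("CaIAA2")])
        (p,) = ph.extract_sister_pairs(ph.UltrametricTree(root),
                                       species_of=lambda g: g[:2])
        assert p.pair_class == "ortholog"

    def test_sister_pairs_have_disjoint_leaves(self, soy_dataset):
        # cherries partition distinct leaves by construction
        prots = [p for p in soy_dataset.proteome
                 if p.id in set(soy_dataset.catalog.gene_ids)][:12]
        alns = [ph.global_align(a, b) for i, a in enumerate(prots)
                for b in prots[i + 1:]]
        tree = ph.upgma(ph.distance_matrix(alns, [p.id for p in prots]))
        pairs = ph.extract_sister_pairs(tree, species_of=lambda g: g[:2])
        leaves = [x for p in pairs for x in (p.id_a, p.id_b)]
        assert len(leaves) == len(set(leaves))
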