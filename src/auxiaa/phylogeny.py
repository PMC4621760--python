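"""Protein alignment, UPGMA trees, bootstrap support and sister pairs.

Pairwise distances come from global (Needleman-Wunsch) alignments under
BLOSUM62 with affine gaps; a gap of length *k* costs
``|gap_open| + (k-1)*|gap_extend|``.  The distance between two proteins is
``1 - fractional identity``.  Trees are built with classic UPGMA
(size-weighted arithmetic mean, node height = distance/2), which yields
ultrametric trees and recovers the generating tree exactly on ultrametric
input.  Bootstrap support resamples alignment columns with replacement and
counts the fraction of replicate trees containing each clade of the
full-data tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .formats import SeqRecord

DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -1.0

_GAP = "-"


def _blosum62():
    return substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# Pairwise alignment


@dataclass
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    percent_similarity: float


def global_align(
    a: SeqRecord,
    b: SeqRecord,
    substitution_matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gap penalties.

    ``percent_identity`` counts identical columns over all alignment
    columns; ``percent_similarity`` additionally counts columns whose
    residue pair scores positively in the substitution matrix.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align an empty sequence")
    matrix = substitution_matrix if substitution_matrix is not None else _blosum62()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = next(iter(aligner.align(a.sequence, b.sequence)))
    sa, sb = str(aln[0]), str(aln[1])
    ncol = len(sa)
    ident = sum(x == y for x, y in zip(sa, sb))
    similar = ident
    for x, y in zip(sa, sb):
        if x != y and x != _GAP and y != _GAP and matrix[x, y] > 0:
            similar += 1
    return PairwiseAlignment(
        id_a=a.id,
        id_b=b.id,
        aligned_a=sa,
        aligned_b=sb,
        score=float(aln.score),
        percent_identity=100.0 * ident / ncol,
        percent_similarity=100.0 * similar / ncol,
    )


# ---------------------------------------------------------------------------
# Distance matrices


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def get(self, i: str, j: str) -> float:
        return float(self.values[self.labels.index(i), self.labels.index(j)])


def distance_matrix(alignments: list[PairwiseAlignment], labels=None) -> DistanceMatrix:
    """d = 1 - fractional identity, from all-pairs alignments."""
    if labels is None:
        labels = sorted({a.id_a for a in alignments} | {a.id_b for a in alignments})
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n))
    seen = np.eye(n, dtype=bool)
    for a in alignments:
        i, j = index[a.id_a], index[a.id_b]
        D[i, j] = D[j, i] = 1.0 - a.percent_identity / 100.0
        seen[i, j] = seen[j, i] = True
    if not seen.all():
        i, j = np.argwhere(~seen)[0]
        raise ValueError(f"missing alignment for pair ({labels[i]}, {labels[j]})")
    return DistanceMatrix(labels=list(labels), values=D)


def msa_distance_matrix(msa: dict[str, str]) -> DistanceMatrix:
    """Pairwise p-distances over MSA columns where neither row is gapped."""
    labels = list(msa)
    arr = np.array([list(msa[l]) for l in labels])
    n = len(labels)
    D = np.zeros((n, n))
    nongap = arr != _GAP
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            tot = int(both.sum())
            if tot == 0:
                d = 1.0
            else:
                d = 1.0 - float((arr[i][both] == arr[j][both]).sum()) / tot
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels=labels, values=D)


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    label: str | None = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf():
            return [self]
        return [l for c in self.children for l in c.leaves()]


@dataclass
class UltrametricTree:
    root: TreeNode

    def leaf_labels(self) -> list[str]:
        return [l.label for l in self.root.leaves()]

    def internal_nodes(self):
        out = []

        def walk(n):
            if not n.is_leaf():
                out.append(n)
                for c in n.children:
                    walk(c)

        walk(self.root)
        return out

    def clades(self) -> set[frozenset]:
        """Leaf-label sets of all internal nodes (root included)."""
        return {
            frozenset(l.label for l in n.leaves()) for n in self.internal_nodes()
        }


def upgma(D: DistanceMatrix) -> UltrametricTree:
    """Classic UPGMA: merge the closest clusters, size-weighted mean update.

    Node height is half the merge distance.  Ties are broken by the
    lexicographically smallest (label_i, label_j) pair, where a cluster's
    label is its smallest leaf label — deterministic by construction.
    """
    n = len(D.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least two taxa")
    nodes = [TreeNode(label=l, height=0.0) for l in D.labels]
    key = list(D.labels)  # smallest leaf label per active cluster
    sizes = [1] * n
    dist = D.values.astype(float).copy()
    active = list(range(n))
    while len(active) > 1:
        idx = np.array(active)
        sub = dist[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        vals = sub[iu]
        d = float(vals.min())
        ties = np.flatnonzero(vals == d)
        best = None
        for t in ties:
            i, j = idx[iu[0][t]], idx[iu[1][t]]
            pair_key = tuple(sorted((key[i], key[j])))
            if best is None or pair_key < best[0]:
                best = (pair_key, i, j)
        _, i, j = best
        if key[j] < key[i]:
            i, j = j, i
        new = TreeNode(height=d / 2.0, children=[nodes[i], nodes[j]])
        ni, nj = sizes[i], sizes[j]
        newdist = (ni * dist[i, :] + nj * dist[j, :]) / (ni + nj)
        k = len(nodes)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[k, : k] = newdist
        dist[: k, k] = newdist
        nodes.append(new)
        sizes.append(ni + nj)
        key.append(min(key[i], key[j]))
        active = [a for a in active if a not in (i, j)] + [k]
    return UltrametricTree(root=nodes[active[0]])


# ---------------------------------------------------------------------------
# Progressive MSA


def _profile_align(prof_a, prof_b, matrix, gap_open, gap_extend, alphabet):
    """Global profile-profile alignment; column score = mean pairwise
    substitution score between non-gap residues of the two columns."""
    S = np.array([[matrix[x, y] for y in alphabet] for x in alphabet], dtype=float)
    aidx = {c: i for i, c in enumerate(alphabet)}

    def col_freqs(profile):
        rows = list(profile.values())
        L = len(rows[0])
        F = np.zeros((L, len(alphabet)))
        for r in rows:
            for p, c in enumerate(r):
                if c != _GAP:
                    F[p, aidx[c]] += 1
        tot = F.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1
        return F / tot

    FA, FB = col_freqs(prof_a), col_freqs(prof_b)
    # mean substitution score between columns i of A and j of B
    score_ij = FA @ S @ FB.T
    la, lb = score_ij.shape
    NEG = -1e18
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (A consumed)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, la + 1):
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        sm = score_ij[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        best_prev = np.maximum(np.maximum(prevM, prevX), prevY)
        Mi[1:] = best_prev[:-1] + sm
        Xi[:] = np.maximum(prevM + gap_open, prevX + gap_extend)
        Xi[:] = np.maximum(Xi, prevY + gap_open)
        for j in range(1, lb + 1):
            Yi[j] = max(Mi[j - 1] + gap_open, Yi[j - 1] + gap_extend,
                        Xi[j - 1] + gap_open)
    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    path = []
    while i > 0 or j > 0:
        if state == 0:
            path.append("M")
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            target = M[i, j] - score_ij[i - 1, j - 1]
            state = int(np.argmin(np.abs(np.array(prev) - target)))
            i, j = i - 1, j - 1
        elif state == 1:
            path.append("X")
            prev = [M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                    Y[i - 1, j] + gap_open]
            state = int(np.argmin(np.abs(np.array(prev) - X[i, j])))
            i -= 1
        else:
            path.append("Y")
            prev = [M[i, j - 1] + gap_open, X[i, j - 1] + gap_open,
                    Y[i, j - 1] + gap_extend]
            state = int(np.argmin(np.abs(np.array(prev) - Y[i, j])))
            j -= 1
    path.reverse()
    out_a = {k: [] for k in prof_a}
    out_b = {k: [] for k in prof_b}
    pa = pb = 0
    for step in path:
        if step in ("M", "X"):
            for k, r in prof_a.items():
                out_a[k].append(r[pa])
            pa += 1
        else:
            for k in prof_a:
                out_a[k].append(_GAP)
        if step in ("M", "Y"):
            for k, r in prof_b.items():
                out_b[k].append(r[pb])
            pb += 1
        else:
            for k in prof_b:
                out_b[k].append(_GAP)
    merged = {k: "".join(v) for k, v in out_a.items()}
    merged.update({k: "".join(v) for k, v in out_b.items()})
    return merged


def progressive_msa(
    sequences: list[SeqRecord],
    guide: UltrametricTree,
    substitution_matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> dict[str, str]:
    """Merge sequence profiles in guide-tree post-order.

    Returns a mapping id -> gapped row; every row has equal length and
    ungaps back to the input sequence.
    """
    if len(sequences) < 2:
        raise ValueError("progressive MSA needs at least two sequences")
    seq_by_id = {s.id: s.sequence for s in sequences}
    if set(seq_by_id) != set(guide.leaf_labels()):
        raise ValueError("guide tree leaves do not match sequence ids")
    matrix = substitution_matrix if substitution_matrix is not None else _blosum62()
    alphabet = "ACDEFGHIKLMNPQRSTVWY"

    def build(node) -> dict[str, str]:
        if node.is_leaf():
            return {node.label: seq_by_id[node.label]}
        prof = build(node.children[0])
        for child in node.children[1:]:
            prof = _profile_align(
                prof, build(child), matrix, gap_open, gap_extend, alphabet
            )
        return prof

    return build(guide.root)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(
    msa: dict[str, str],
    n_replicates: int = 1000,
    seed: int = 0,
    tree: UltrametricTree | None = None,
) -> UltrametricTree:
    """Column bootstrap: resample MSA columns, rebuild distance+UPGMA,
    annotate each internal node of the full-data tree with the fraction of
    replicates containing its clade."""
    labels = list(msa)
    ncol = len(next(iter(msa.values())))
    if ncol < 2:
        raise ValueError("bootstrap needs an MSA with at least 2 columns")
    if tree is None:
        tree = upgma(msa_distance_matrix(msa))
    arr = np.array([list(msa[l]) for l in labels])
    codes = np.zeros(arr.shape, dtype=np.int16)
    letters = np.unique(arr)
    for k, c in enumerate(letters):
        codes[arr == c] = k
    gap_code = int(np.where(letters == _GAP)[0][0]) if _GAP in letters else -1

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {c: 0 for c in tree.clades()}
    n = len(labels)
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        sub = codes[:, cols]
        nongap = sub != gap_code
        D = np.zeros((n, n))
        for i in range(n):
            both = nongap[i] & nongap[i + 1 :]
            eq = (sub[i] == sub[i + 1 :]) & both
            tot = both.sum(axis=1)
            with np.errstate(invalid="ignore"):
                d = 1.0 - eq.sum(axis=1) / np.where(tot == 0, 1, tot)
            d[tot == 0] = 1.0
            D[i, i + 1 :] = d
            D[i + 1 :, i] = d
        rep = upgma(DistanceMatrix(labels=labels, values=D))
        rep_clades = rep.clades()
        for c in counts:
            if c in rep_clades:
                counts[c] += 1
    for node in tree.internal_nodes():
        clade = frozenset(l.label for l in node.leaves())
        node.support = counts[clade] / n_replicates
    return tree


# ---------------------------------------------------------------------------
# Sister pairs


@dataclass
class SisterPair:
    id_a: str
    id_b: str
    pair_class: str  # paralog | ortholog


def extract_sister_pairs(tree: UltrametricTree, species_of) -> list[SisterPair]:
    """Report every cherry (internal node with two leaf children); paralog
    when both leaves belong to the same species."""
    pairs = []
    for node in tree.internal_nodes():
        if len(node.children) == 2 and all(c.is_leaf() for c in node.children):
            a, b = sorted(c.label for c in node.children)
            cls = "paralog" if species_of(a) == species_of(b) else "ortholog"
            pairs.append(SisterPair(id_a=a, id_b=b, pair_class=cls))
    return pairs
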