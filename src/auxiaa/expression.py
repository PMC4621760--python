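"""Expression analysis: RPKM, heatmap ordering, DE calls, paralog divergence.

RPKM (reads per kilobase of transcript per million mapped reads) is
``count * 1e9 / (library_size * gene_length_bp)``.  Differential
expression follows the classic screen: a gene is DE between two
conditions when the fold change is at least 2 (either direction) *and* a
two-sided t-test gives P <= 0.05; no multiple-testing correction is
applied, matching the original screen.  Paralog expression divergence is
judged by the Pearson correlation of the two genes' log2(RPKM+1) profiles
across tissues: conserved when r >= 0.8 (a package convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class CountMatrix:
    """Raw counts (genes x samples) with gene lengths (bp) and per-sample
    library sizes (total mapped reads)."""

    counts: pd.DataFrame
    gene_lengths: pd.Series  # bp
    library_sizes: pd.Series  # reads

    def __post_init__(self) -> None:
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
            raise ValueError("every gene needs a positive length")
        if self.library_sizes.isna().any() or (self.library_sizes <= 0).any():
            raise ValueError("every sample needs a positive library size")


def rpkm(counts: CountMatrix) -> pd.DataFrame:
    """count * 1e9 / (library_size * gene_length_bp), per cell."""
    c = counts.counts.astype(float)
    denom = np.outer(counts.gene_lengths.values, counts.library_sizes.values)
    return pd.DataFrame(
        c.values * 1e9 / denom, index=c.index, columns=c.columns
    )


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise (x - mean)/sd with sample (n-1) sd; constant rows -> 0."""
    if matrix.shape[1] < 2:
        raise ValueError("row z-scores need at least 2 samples")
    vals = matrix.values.astype(float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(vals)
    nz = sd[:, 0] > 0
    out[nz] = (vals[nz] - mean[nz]) / sd[nz]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def hclust_order(matrix: pd.DataFrame, method: str = "complete", metric: str = "euclidean"):
    """Agglomerative clustering of rows (heatmap order).

    Returns ``(linkage_matrix, leaf_order)``; merge heights are
    non-decreasing for complete linkage and ties resolve deterministically.
    """
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least 2 rows")
    Z = hierarchy.linkage(pdist(matrix.values, metric=metric), method=method)
    order = hierarchy.leaves_list(Z)
    return Z, [matrix.index[i] for i in order]


@dataclass
class DEResult:
    gene_id: str
    fold_change: float
    p_value: float
    is_de: bool


def call_de(
    control, treatment, gene_id: str = "", epsilon: float = 1.0,
    fold_threshold: float = 2.0, alpha: float = 0.05, welch: bool = True,
) -> DEResult:
    """Two-group DE call: fold = (mean_t + eps)/(mean_c + eps); DE iff
    fold >= 2 or <= 0.5 *and* two-sided t-test P <= 0.05 (Welch by
    default; set ``welch=False`` for the pooled-variance test)."""
    control = np.asarray(control, dtype=float)
    treatment = np.asarray(treatment, dtype=float)
    if len(control) < 2 or len(treatment) < 2:
        raise ValueError("DE calls need at least 2 replicates per group")
    mc, mt = control.mean(), treatment.mean()
    if mc == 0.0 or mt == 0.0:  # pseudo-count only where a ratio is undefined
        fold = (mt + epsilon) / (mc + epsilon)
    else:
        fold = mt / mc
    if np.all(control == control[0]) and np.all(treatment == treatment[0]) and (
        control[0] == treatment[0]
    ):
        return DEResult(gene_id, 1.0 if control[0] == 0 else fold, 1.0, False)
    t, p = stats.ttest_ind(treatment, control, equal_var=not welch)
    p = 1.0 if np.isnan(p) else float(p)
    is_de = (fold >= fold_threshold or fold <= 1.0 / fold_threshold) and p <= alpha
    return DEResult(gene_id, float(fold), p, bool(is_de))


@dataclass
class ParalogDivergence:
    id_a: str
    id_b: str
    pearson_r: float | None
    verdict: str  # conserved | diverged
    undefined: bool = False


def paralog_divergence(
    pair: tuple[str, str], expr: pd.DataFrame, r_threshold: float = 0.8
) -> ParalogDivergence:
    """Pearson r of the pair's log2(RPKM+1) profiles across samples;
    conserved iff r >= threshold.  A zero-variance profile leaves r
    undefined and the pair is called diverged with a flag."""
    a, b = pair
    for g in pair:
        if g not in expr.index:
            raise KeyError(f"gene {g} absent from expression matrix")
    if expr.shape[1] < 3:
        raise ValueError("paralog divergence needs at least 3 samples")
    xa = np.log2(expr.loc[a].values.astype(float) + 1.0)
    xb = np.log2(expr.loc[b].values.astype(float) + 1.0)
    if xa.std() == 0 or xb.std() == 0:
        return ParalogDivergence(a, b, None, "diverged", undefined=True)
    r = float(np.corrcoef(xa, xb)[0, 1])
    return ParalogDivergence(a, b, r, "conserved" if r >= r_threshold else "diverged")


def tissue_specificity(expr: pd.DataFrame) -> pd.DataFrame:
    """Descriptive aids: per-gene max-tissue share and tau index."""
    vals = np.log2(expr.values.astype(float) + 1.0)
    total = vals.sum(axis=1)
    total[total == 0] = 1.0
    share = vals.max(axis=1) / total
    mx = vals.max(axis=1, keepdims=True)
    mx[mx == 0] = 1.0
    tau = (1.0 - vals / mx).sum(axis=1) / (vals.shape[1] - 1)
    return pd.DataFrame(
        {
            "max_tissue": expr.columns[np.argmax(vals, axis=1)],
            "max_share": share,
            "tau": tau,
        },
        index=expr.index,
    )
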