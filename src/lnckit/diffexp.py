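"""Pairwise differential expression with BH-FDR, plus sample clustering.

Each comparison applies a two-sided pooled-variance (equal-variance)
Student's t-test on log2(FPKM + 1) values, adjusts the raw p-values with
the Benjamini-Hochberg step-up procedure across all transcripts tested in
that comparison, and calls significance at ``p_adj < alpha``.  Fold changes
are pseudocounted group-mean ratios on the raw FPKM scale and reported with
the signed convention common in expression tables: a ratio below one is
printed as the negative reciprocal (e.g. 0.5 -> -2.0).

Sample structure is summarised by unsupervised hierarchical clustering with
average linkage on the distance 1 - PCC between sample profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, log_transform

__all__ = [
    "DERecord",
    "ClusterTree",
    "fold_change",
    "student_t_test",
    "bh_adjust",
    "call_de",
    "intersect_common_de",
    "hierarchical_cluster",
    "DE_COLUMNS",
]

#: Schema of the DataFrame returned by :func:`call_de`.
DE_COLUMNS = (
    "transcript_id",
    "group_a",
    "group_b",
    "mean_a",
    "mean_b",
    "fold_change",
    "log2_fc",
    "p_raw",
    "p_adj",
    "direction",
    "significant",
)

_VARIANCE_FLOOR = 1e-8


@dataclass(frozen=True)
class DERecord:
    """One transcript's result in one pairwise comparison."""

    transcript_id: str
    group_a: str
    group_b: str
    fold_change: float
    log2_fc: float
    p_raw: float
    p_adj: float
    direction: str  # "up" | "down" (group_a relative to group_b)
    significant: bool

    @classmethod
    def from_row(cls, row: pd.Series) -> "DERecord":
        return cls(
            transcript_id=row["transcript_id"],
            group_a=row["group_a"],
            group_b=row["group_b"],
            fold_change=float(row["fold_change"]),
            log2_fc=float(row["log2_fc"]),
            p_raw=float(row["p_raw"]),
            p_adj=float(row["p_adj"]),
            direction=row["direction"],
            significant=bool(row["significant"]),
        )


def fold_change(mean_a: float, mean_b: float, pseudocount: float = 1.0) -> float:
    """Signed pseudocounted fold change of group a over group b.

    ratio = (mean_a + pc) / (mean_b + pc); ratios below 1 are reported as
    ``-1/ratio`` so down-regulation prints as a negative fold.
    """
    if mean_a < 0 or mean_b < 0 or pseudocount <= 0:
        raise ValueError("means must be >= 0 and pseudocount > 0")
    ratio = (mean_a + pseudocount) / (mean_b + pseudocount)
    return ratio if ratio >= 1.0 else -1.0 / ratio


def _pooled_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised two-sided pooled-variance t-test p-values along axis 1."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    ssa = ((a - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((b - mb[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    sp2 = np.maximum((ssa + ssb) / df, _VARIANCE_FLOOR)
    t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return 2.0 * stats.t.sf(np.abs(t), df)


def student_t_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided pooled-variance two-sample t-test.

    A variance floor (1e-8 on the pooled estimate) keeps perfectly separated
    constant groups finite; two identical constant groups give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("each group needs >= 2 finite values")
    return float(_pooled_t(a[None, :], b[None, :])[0])


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_i = min over j >= i (rank order) of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential expression of ``group_a`` vs ``group_b`` for every transcript.

    Returns a DataFrame with :data:`DE_COLUMNS`; the t-test runs on
    log2(FPKM + 1), fold change on raw FPKM group means, and BH adjustment
    spans all transcripts of the comparison.
    """
    sa = expr.samples_in_group(group_a)
    sb = expr.samples_in_group(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs >= 2 samples")
    raw = expr.values
    logged = log_transform(expr, pseudocount=1.0, base=2.0)
    p_raw = _pooled_t(logged[sa].to_numpy(), logged[sb].to_numpy())
    p_adj = bh_adjust(p_raw)
    mean_a = raw[sa].mean(axis=1).to_numpy()
    mean_b = raw[sb].mean(axis=1).to_numpy()
    ratio = (mean_a + pseudocount) / (mean_b + pseudocount)
    fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    out = pd.DataFrame(
        {
            "transcript_id": list(raw.index),
            "group_a": group_a,
            "group_b": group_b,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "log2_fc": np.log2(ratio),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": np.where(ratio > 1.0, "up", "down"),
            "significant": p_adj < alpha,
        }
    )
    return out


def intersect_common_de(de_1, de_2) -> list[str]:
    """Order-stable intersection of two significant-id collections.

    Output preserves the order of ``de_1``.
    """
    set2 = set(de_2)
    seen: set[str] = set()
    out = []
    for x in de_1:
        if x in set2 and x not in seen:
            out.append(x)
            seen.add(x)
    return out


@dataclass
class ClusterTree:
    """Average-linkage merge history of samples under distance 1 - PCC."""

    linkage: np.ndarray
    labels: list[str]

    def cut(self, k: int) -> dict[str, int]:
        """Partition the samples into ``k`` clusters (1-based cluster ids)."""
        if not 1 <= k <= len(self.labels):
            raise ValueError(f"k must be in [1, {len(self.labels)}]")
        assignment = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in assignment)))

    def to_newick(self) -> str:
        """Newick text of the tree with merge distances as branch lengths."""
        root = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_dist) -> str:
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return fmt(root, root.dist) + ";"


def hierarchical_cluster(
    expr: ExpressionMatrix, transcript_subset: Sequence[str]
) -> ClusterTree:
    """Cluster samples over a transcript subset (e.g. the DE set).

    Distance is 1 - Pearson correlation between sample profiles of
    log10(FPKM + 1) values; linkage is average (UPGMA).  Samples with zero
    variance over the subset are excluded with a warning.
    """
    ids = list(transcript_subset)
    if not ids:
        raise ValueError("empty transcript subset")
    logged = log_transform(expr.subset(ids), pseudocount=1.0, base=10.0)
    variances = logged.var(axis=0)
    keep = [s for s in logged.columns if variances[s] > 0]
    dropped = [s for s in logged.columns if variances[s] == 0]
    if dropped:
        warnings.warn(f"excluded zero-variance samples: {dropped}", stacklevel=2)
    if len(keep) < 2:
        raise ValueError("need >= 2 samples with variance for clustering")
    corr = np.corrcoef(logged[keep].to_numpy().T)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return ClusterTree(linkage=z, labels=keep)
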