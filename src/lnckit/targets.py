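"""cis/trans lncRNA target prediction, neighbor correlation, enrichment.

A protein-coding gene is a candidate *cis* target of a lncRNA when its
locus lies within a genomic-distance window (default 100 kb, inclusive) of
the lncRNA on the same chromosome; it is a candidate *trans* target when
it is co-expressed with the lncRNA (|PCC| strictly above a threshold,
default 0.95) while lying beyond the window or on a different chromosome.
Distances are span gaps between the lncRNA transcript and the union span
of the coding locus, so an overlapping pair has distance 0.

Correlations are Pearson coefficients over all samples on log10(FPKM + 1);
the lncRNA side uses transcript-level expression, the coding side the
locus-level sum of its isoforms.

Gene-set over-representation uses the upper-tail hypergeometric test with
BH adjustment across terms, with the rich factor k / K (foreground hits
over background term size) reported per term.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationSet, TranscriptModel, UNREACHABLE
from .catalog import CatalogEntry
from .diffexp import bh_adjust, student_t_test
from .expression import ExpressionMatrix, log_transform

__all__ = [
    "TargetPair",
    "PairClassSummary",
    "EnrichmentResult",
    "cis_targets",
    "trans_targets",
    "random_pair_null",
    "neighbor_correlation_analysis",
    "hypergeometric_enrichment",
    "rich_factor",
    "locus_expression",
    "read_gmt",
    "write_gmt",
    "write_pairs",
]


@dataclass(frozen=True)
class TargetPair:
    """A predicted (lncRNA transcript, coding locus) regulatory link."""

    lncrna_id: str
    mrna_id: str
    mode: str  # "cis" | "trans"
    distance: float  # bases; inf when on different chromosomes
    pcc: float = float("nan")

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans"):
            raise ValueError(f"invalid mode: {self.mode!r}")


@dataclass
class PairClassSummary:
    """PCC distribution of one pair class (lnc:cis-mRNA, mRNA:cis-mRNA, random)."""

    name: str
    pccs: np.ndarray

    @property
    def mean_pcc(self) -> float:
        return float(np.mean(self.pccs))

    @property
    def n(self) -> int:
        return int(self.pccs.size)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one gene-set term."""

    term_id: str
    k: int  # foreground genes in term
    K: int  # background genes in term
    n: int  # foreground size
    N: int  # background size
    p_raw: float
    q: float
    rich_factor: float
    significant: bool


def _span_gap(t: TranscriptModel, locus_start: int, locus_end: int) -> float:
    return float(max(0, max(t.start, locus_start) - min(t.end, locus_end)))


def _lnc_transcripts(lncrnas) -> list[TranscriptModel]:
    out = []
    for item in lncrnas:
        out.append(item.transcript if isinstance(item, CatalogEntry) else item)
    return out


def locus_expression(annot: AnnotationSet, expr: ExpressionMatrix) -> pd.DataFrame:
    """Locus x sample FPKM by summing member transcript rows present in expr."""
    rows = {}
    have = set(expr.transcript_ids)
    for locus in annot.locus_ids:
        tids = [t.transcript_id for t in annot.in_locus(locus) if t.transcript_id in have]
        if tids:
            rows[locus] = expr.values.loc[tids].sum(axis=0)
    return pd.DataFrame(rows).T


def _log10p1(frame: pd.DataFrame) -> pd.DataFrame:
    return np.log10(frame + 1.0)


def _pcc_table(
    lnc_log: pd.DataFrame, gene_log: pd.DataFrame
) -> tuple[np.ndarray, list[str], list[str]]:
    """All-pairs correlation between lnc rows and gene rows (NaN where constant)."""
    a = lnc_log.to_numpy(dtype=float)
    b = gene_log.to_numpy(dtype=float)
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1))
    bsd = np.sqrt((bz**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / np.outer(asd, bsd)
    return np.clip(r, -1.0, 1.0), list(lnc_log.index), list(gene_log.index)


def cis_targets(
    lncrnas: Sequence,
    mrnas: AnnotationSet,
    expr: ExpressionMatrix | None = None,
    window: int = 100_000,
) -> list[TargetPair]:
    """All (lncRNA, coding locus) pairs within the cis window (inclusive).

    ``lncrnas`` may be catalog entries or bare transcript models.  When an
    expression matrix is given the pair's PCC over all samples is attached
    (NaN if either side is constant).
    """
    ts = _lnc_transcripts(lncrnas)
    spans = {locus: mrnas.locus_span(locus) for locus in mrnas.locus_ids}
    pcc_lookup = None
    if expr is not None:
        have = set(expr.transcript_ids)
        lnc_ids = [t.transcript_id for t in ts if t.transcript_id in have]
        lnc_log = _log10p1(expr.values.loc[lnc_ids])
        gene_log = _log10p1(locus_expression(mrnas, expr))
        r, ridx, cidx = _pcc_table(lnc_log, gene_log)
        pcc_lookup = (
            {t: i for i, t in enumerate(ridx)},
            {g: j for j, g in enumerate(cidx)},
            r,
        )
    out: list[TargetPair] = []
    for t in ts:
        for locus, span in spans.items():
            if span.chrom != t.chrom:
                continue
            d = _span_gap(t, span.start, span.end)
            if d <= window:
                pcc = float("nan")
                if pcc_lookup is not None:
                    li, gi, r = pcc_lookup
                    if t.transcript_id in li and locus in gi:
                        pcc = float(r[li[t.transcript_id], gi[locus]])
                out.append(TargetPair(t.transcript_id, locus, "cis", d, pcc))
    return out


def trans_targets(
    lncrnas: Sequence,
    mrnas: AnnotationSet,
    expr: ExpressionMatrix,
    pcc_min: float = 0.95,
    window: int = 100_000,
) -> list[TargetPair]:
    """Co-expressed distant pairs: |PCC| > pcc_min (strict) and beyond the
    window or on a different chromosome."""
    ts = _lnc_transcripts(lncrnas)
    have = set(expr.transcript_ids)
    ts = [t for t in ts if t.transcript_id in have]
    lnc_log = _log10p1(expr.values.loc[[t.transcript_id for t in ts]])
    gene_log = _log10p1(locus_expression(mrnas, expr))
    r, _ridx, cidx = _pcc_table(lnc_log, gene_log)
    spans = {locus: mrnas.locus_span(locus) for locus in cidx}
    out: list[TargetPair] = []
    for i, t in enumerate(ts):
        for j, locus in enumerate(cidx):
            pcc = r[i, j]
            if not np.isfinite(pcc) or abs(pcc) <= pcc_min:
                continue
            span = spans[locus]
            d = (
                UNREACHABLE
                if span.chrom != t.chrom
                else _span_gap(t, span.start, span.end)
            )
            if d > window:
                out.append(TargetPair(t.transcript_id, locus, "trans", d, float(pcc)))
    return out


def random_pair_null(
    mrna_ids: Sequence[str], n_pairs: int, seed: int
) -> list[tuple[str, str]]:
    """Sample distinct unordered coding-gene pairs uniformly without replacement."""
    ids = list(mrna_ids)
    m = len(ids)
    if m < 2:
        raise ValueError("need >= 2 genes to form pairs")
    total = m * (m - 1) // 2
    if n_pairs > total:
        raise ValueError(f"requested {n_pairs} pairs but only {total} exist")
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, int]] = set()
    out: list[tuple[str, str]] = []
    while len(out) < n_pairs:
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        out.append((ids[key[0]], ids[key[1]]))
    return out


def neighbor_correlation_analysis(
    catalog: Sequence,
    mrnas: AnnotationSet,
    expr: ExpressionMatrix,
    window: int = 100_000,
    seed: int = 0,
) -> tuple[dict[str, PairClassSummary], dict[str, float]]:
    """Compare neighbor-pair correlation classes against a random-pair null.

    Classes: ``lnc_cis`` (lncRNA vs coding neighbor within the window),
    ``mrna_cis`` (coding locus pairs within the window) and ``random``
    (uniformly sampled coding pairs, count-matched to ``lnc_cis``).  Returns
    per-class PCC summaries plus pooled-variance t-test p-values for
    lnc_cis-vs-random, mrna_cis-vs-random and lnc_cis-vs-mrna_cis.
    Constant-expression pairs are dropped before testing.
    """
    gene_log = _log10p1(locus_expression(mrnas, expr))
    gene_ok = gene_log.index[gene_log.var(axis=1) > 0]
    gene_log = gene_log.loc[gene_ok]

    lnc_pccs = np.array(
        [
            p.pcc
            for p in cis_targets(catalog, mrnas, expr, window)
            if np.isfinite(p.pcc)
        ]
    )

    spans = {locus: mrnas.locus_span(locus) for locus in gene_log.index}
    loci = sorted(gene_log.index)
    mrna_pccs = []
    for i, la in enumerate(loci):
        for lb in loci[i + 1 :]:
            sa, sb = spans[la], spans[lb]
            if sa.chrom != sb.chrom:
                continue
            gap = max(0, max(sa.start, sb.start) - min(sa.end, sb.end))
            if gap <= window:
                mrna_pccs.append(_row_pcc(gene_log, la, lb))
    mrna_pccs = np.array([p for p in mrna_pccs if np.isfinite(p)])

    if lnc_pccs.size < 2 or mrna_pccs.size < 2:
        raise ValueError("a neighbor-pair class has fewer than 2 usable pairs")

    pairs = random_pair_null(list(gene_log.index), int(lnc_pccs.size), seed)
    rand_pccs = np.array(
        [p for p in (_row_pcc(gene_log, a, b) for a, b in pairs) if np.isfinite(p)]
    )

    summaries = {
        "lnc_cis": PairClassSummary("lnc_cis", lnc_pccs),
        "mrna_cis": PairClassSummary("mrna_cis", mrna_pccs),
        "random": PairClassSummary("random", rand_pccs),
    }
    pvalues = {
        "lnc_cis_vs_random": student_t_test(lnc_pccs, rand_pccs),
        "mrna_cis_vs_random": student_t_test(mrna_pccs, rand_pccs),
        "lnc_cis_vs_mrna_cis": student_t_test(lnc_pccs, mrna_pccs),
    }
    return summaries, pvalues


def _row_pcc(frame: pd.DataFrame, a: str, b: str) -> float:
    x = frame.loc[a].to_numpy(dtype=float)
    y = frame.loc[b].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))


def rich_factor(k: int, K: int) -> float:
    """Enriched-gene count over the background gene count of the term."""
    if K <= 0:
        raise ValueError("term has no background genes (K = 0)")
    if not 0 <= k <= K:
        raise ValueError(f"k = {k} outside [0, K = {K}]")
    return k / K


def hypergeometric_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    gene_sets: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation per term, BH across terms.

    For a term with K background genes, foreground of size n from a
    background of size N and k foreground hits: p = P(X >= k) for
    X ~ Hypergeom(N, K, n).  Terms are intersected with the background;
    empty intersections are skipped.  Significance is q < alpha.
    """
    bg = set(background)
    fg = set(foreground)
    if not fg <= bg:
        raise ValueError(f"foreground not contained in background: {sorted(fg - bg)[:5]}")
    N, n = len(bg), len(fg)
    rows = []
    for term_id in sorted(gene_sets):
        term = set(gene_sets[term_id]) & bg
        K = len(term)
        if K == 0:
            continue
        k = len(term & fg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, k, K, p))
    if not rows:
        return []
    q = bh_adjust([r[3] for r in rows])
    return [
        EnrichmentResult(
            term_id=term_id,
            k=k,
            K=K,
            n=n,
            N=N,
            p_raw=p,
            q=float(qi),
            rich_factor=rich_factor(k, K),
            significant=bool(qi < alpha),
        )
        for (term_id, k, K, p), qi in zip(rows, q)
    ]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: term <tab> description <tab> gene ids.  Returns term -> genes."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            out[fields[0]] = [g for g in fields[2:] if g]
    return out


def write_gmt(
    gene_sets: Mapping[str, Sequence[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for term in sorted(gene_sets):
            desc = (descriptions or {}).get(term, "na")
            fh.write("\t".join([term, desc, *gene_sets[term]]) + "\n")


def write_pairs(pairs: Sequence[TargetPair], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "lncrna_id": p.lncrna_id,
                "mrna_id": p.mrna_id,
                "mode": p.mode,
                "distance": p.distance,
                "pcc": p.pcc,
            }
            for p in pairs
        ],
        columns=["lncrna_id", "mrna_id", "mode", "distance", "pcc"],
    ).to_csv(path, sep="\t", index=False)
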