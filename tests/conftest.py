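import numpy as np
import pandas as pd
import pytest

from lnckit.annotation import AnnotationSet, GenomicInterval, TranscriptModel
from lnckit.expression import ExpressionMatrix


def make_transcript(
    tid, exons, chrom="chr1", strand="+", locus=None, biotype="other"
):
    """Build a TranscriptModel from (start, end) exon tuples."""
    return TranscriptModel(
        tid,
        locus or f"loc_{tid}",
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        biotype=biotype,
    )


@pytest.fixture
def make_expr():
    """Factory for small FPKM matrices with a 3x3 group design."""

    def _make(values: dict[str, list[float]], groups=None, unit="FPKM"):
        samples = None
        for v in values.values():
            samples = len(v)
            break
        cols = [f"s{i}" for i in range(samples)]
        if groups is None:
            groups = {c: "g" for c in cols}
        return ExpressionMatrix(
            pd.DataFrame(values, index=cols).T, groups, unit=unit
        )

    return _make


def per_base_exonic_overlap(a, b, strand_mode="ignore"):
    """Brute-force oracle: count bases covered by exons of both transcripts."""
    if a.chrom != b.chrom:
        return 0
    if strand_mode == "same" and a.strand != b.strand:
        return 0
    if strand_mode == "opposite" and (
        a.strand == b.strand or "." in (a.strand, b.strand)
    ):
        return 0
    bases_a = set()
    for e in a.exons:
        bases_a.update(range(e.start, e.end))
    bases_b = set()
    for e in b.exons:
        bases_b.update(range(e.start, e.end))
    return len(bases_a & bases_b)


def random_toy_transcript(rng, chrom="chr1", lo=0, hi=1000, max_exons=3, tid="t"):
    """A random small transcript within [lo, hi) for oracle comparisons."""
    n_exons = int(rng.integers(1, max_exons + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    cuts = sorted(rng.choice(np.arange(lo, hi), size=2 * n_exons, replace=False))
    exons = []
    for i in range(0, 2 * n_exons, 2):
        s, e = int(cuts[i]), int(cuts[i + 1])
        if e == s:
            e += 1
        if exons and s < exons[-1][1]:
            s = exons[-1][1] + 1
            e = max(e, s + 1)
        exons.append((s, e))
    return make_transcript(tid, exons, chrom=chrom, strand=strand)
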