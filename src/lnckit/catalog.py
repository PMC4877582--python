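"""lncRNA catalog construction: filtering, known/novel split, classification.

The identification pipeline takes assembled transcript models and keeps
those that behave like reliable long noncoding RNAs:

1. length   -- spliced length >= 200 nt (the defining lncRNA size cutoff);
2. exons    -- novel models need >= 2 exons (single-exon assemblies are
               fragile); transcripts matching the reference lncRNA
               annotation are exempt;
3. expression -- FPKM >= threshold in at least one sample;
4. coding overlap -- no same-strand exonic overlap with any protein-coding
               transcript (such models are fragments of mRNAs);
5. coding potential -- a provided PhyloCSF-style score must not exceed the
               cutoff; without scores, a longest-ORF surrogate is applied
               when transcript sequences are supplied, otherwise the stage
               passes with a warning.

Survivors are split into known vs novel against a reference lncRNA
annotation (intron-chain identity for spliced models; >= 50 % reciprocal
overlap of the shorter transcript for single-exon models) and classified
by position relative to protein-coding genes as lincRNA, intronic or
antisense.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, TranscriptModel, exonic_overlap
from .expression import ExpressionMatrix, log_transform

__all__ = [
    "FilterParams",
    "FilterResult",
    "CatalogEntry",
    "CatalogStats",
    "MissingExpressionError",
    "filter_candidates",
    "split_known_novel",
    "classify_lncrna",
    "catalog_stats",
    "build_catalog",
    "longest_orf_codons",
    "write_catalog",
    "write_attrition",
]

#: Pipeline order of the attrition stages.
FILTER_STAGES = ("length", "exon_count", "expression", "coding_overlap", "coding_potential")


class MissingExpressionError(ValueError):
    """Assembled transcripts lack expression rows."""


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the candidate filter (all configurable).

    min_length: minimum spliced length in bases (>= 200 by definition).
    min_exons_novel: exon-count floor for models absent from the reference.
    min_fpkm: required maximum FPKM across samples.
    coding_score_max: keep transcripts with provided coding score <= this
        (PhyloCSF convention: lower means less coding).
    orf_max_codons: surrogate cutoff; a longest ORF of fewer codons than
        this counts as noncoding.
    """

    min_length: int = 200
    min_exons_novel: int = 2
    min_fpkm: float = 0.5
    coding_score_max: float = 0.0
    orf_max_codons: int = 100

    def __post_init__(self) -> None:
        if self.min_length < 200:
            raise ValueError("min_length below the 200 nt lncRNA definition")
        for name in ("min_fpkm", "coding_score_max"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class FilterResult:
    """Survivors plus a per-stage attrition log (counts removed, in order)."""

    survivors: list[TranscriptModel]
    attrition: dict[str, int]

    @property
    def n_removed(self) -> int:
        return sum(self.attrition.values())


@dataclass(frozen=True)
class CatalogEntry:
    """An accepted lncRNA with its novelty status and positional class."""

    transcript: TranscriptModel
    novelty: str  # "known" | "novel"
    positional_class: str  # "lincRNA" | "intronic" | "antisense"
    coding_score: float = float("nan")

    def __post_init__(self) -> None:
        if self.novelty not in ("known", "novel"):
            raise ValueError(f"invalid novelty: {self.novelty!r}")
        if self.positional_class not in ("lincRNA", "intronic", "antisense"):
            raise ValueError(f"invalid class: {self.positional_class!r}")


@dataclass
class CatalogStats:
    """Summary of a catalog: sizes, splicing and expression distributions."""

    n_transcripts: int
    n_loci: int
    mean_length: float
    mean_exons: float
    isoforms_per_locus: float
    class_counts: dict[tuple[str, str], int]
    mean_log10_fpkm: pd.Series  # per-transcript mean of log10(FPKM + 1)


_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf_codons(seq: str) -> int:
    """Longest open reading frame (ATG..stop) in codons, over 3 forward frames.

    The sequence is the spliced transcript in sense orientation.  The stop
    codon is not counted.  0 when no complete ORF exists.
    """
    seq = seq.upper()
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, (i - start) // 3)
                start = None
    return best


def _known_lookup(lnc_ref: AnnotationSet | None):
    """Build the reference indices used by the known/novel rule."""
    chains: set[tuple] = set()
    single_by_chrom: dict[str, list[TranscriptModel]] = {}
    if lnc_ref is not None:
        for r in lnc_ref:
            if r.n_exons >= 2:
                chains.add(r.intron_chain)
            else:
                single_by_chrom.setdefault(r.chrom, []).append(r)
    return chains, single_by_chrom


def _matches_reference(
    t: TranscriptModel,
    chains: set[tuple],
    single_by_chrom: dict[str, list[TranscriptModel]],
) -> bool:
    if t.n_exons >= 2:
        return t.intron_chain in chains
    for r in single_by_chrom.get(t.chrom, ()):
        if r.strand != t.strand:
            continue
        ov = exonic_overlap(t, r, strand_mode="same")
        if ov >= 0.5 * min(t.length, r.length):
            return True
    return False


def filter_candidates(
    assembled: AnnotationSet,
    coding_ref: AnnotationSet,
    expr: ExpressionMatrix,
    scores: Mapping[str, float] | None = None,
    params: FilterParams = FilterParams(),
    lnc_ref: AnnotationSet | None = None,
    sequences: Mapping[str, str] | None = None,
) -> FilterResult:
    """Run the five-stage lncRNA candidate filter over assembled transcripts.

    Every assembled transcript must have an expression row (``expr`` in
    FPKM); ``lnc_ref`` provides the exon-count exemption for transcripts
    matching the reference lncRNA annotation.  Returns the survivors plus
    an attrition log keyed by stage in pipeline order.
    """
    if expr.unit != "FPKM":
        raise ValueError("filter_candidates expects FPKM expression")
    missing = [t.transcript_id for t in assembled if t.transcript_id not in set(expr.transcript_ids)]
    if missing:
        raise MissingExpressionError(
            f"{len(missing)} transcripts lack expression rows: {missing[:10]}"
        )

    attrition = {stage: 0 for stage in FILTER_STAGES}
    chains, single_ref = _known_lookup(lnc_ref)
    max_fpkm = expr.values.max(axis=1)

    current = list(assembled)

    kept = []
    for t in current:
        if t.length >= params.min_length:
            kept.append(t)
        else:
            attrition["length"] += 1
    current = kept

    kept = []
    for t in current:
        if t.n_exons >= params.min_exons_novel or _matches_reference(t, chains, single_ref):
            kept.append(t)
        else:
            attrition["exon_count"] += 1
    current = kept

    kept = []
    for t in current:
        if max_fpkm[t.transcript_id] >= params.min_fpkm:
            kept.append(t)
        else:
            attrition["expression"] += 1
    current = kept

    coding_by_chrom: dict[str, list[TranscriptModel]] = {}
    for c in coding_ref:
        coding_by_chrom.setdefault(c.chrom, []).append(c)
    kept = []
    for t in current:
        overlapping = False
        for c in coding_by_chrom.get(t.chrom, ()):
            if c.strand != t.strand or c.end <= t.start or c.start >= t.end:
                continue
            if exonic_overlap(t, c, strand_mode="same") > 0:
                overlapping = True
                break
        if overlapping:
            attrition["coding_overlap"] += 1
        else:
            kept.append(t)
    current = kept

    kept = []
    n_unscored = 0
    for t in current:
        tid = t.transcript_id
        if scores is not None and tid in scores:
            ok = scores[tid] <= params.coding_score_max
        elif sequences is not None and tid in sequences:
            ok = longest_orf_codons(sequences[tid]) < params.orf_max_codons
        else:
            n_unscored += 1
            ok = True
        if ok:
            kept.append(t)
        else:
            attrition["coding_potential"] += 1
    if n_unscored:
        warnings.warn(
            f"{n_unscored} transcripts passed the coding-potential stage "
            "without a score or sequence",
            stacklevel=2,
        )
    return FilterResult(kept, attrition)


def split_known_novel(
    candidates: Sequence[TranscriptModel], lnc_ref: AnnotationSet
) -> dict[str, str]:
    """Label each candidate ``known`` or ``novel`` against a reference catalog.

    A spliced candidate is known iff its intron chain is identical to some
    reference transcript (exon termini may differ); a single-exon candidate
    is known iff it shares >= 50 % same-strand exonic overlap of the shorter
    transcript with a single-exon reference model.
    """
    chains, single_ref = _known_lookup(lnc_ref)
    return {
        t.transcript_id: "known" if _matches_reference(t, chains, single_ref) else "novel"
        for t in candidates
    }


def classify_lncrna(t: TranscriptModel, coding_ref: AnnotationSet) -> str:
    """Positional class of an accepted lncRNA: lincRNA, intronic or antisense.

    Precedence (exon contact is stronger evidence than containment):

    1. ``antisense``  -- any exonic overlap with a protein-coding exon on
       the opposite strand;
    2. ``intronic``   -- the whole span lies inside a single intron of one
       coding transcript (either strand);
    3. fallback for models overlapping a coding span without exon contact
       or single-intron containment (e.g. spanning several introns): if
       every exon sits in some intron of one coding transcript the model is
       ``intronic``, otherwise ``lincRNA``;
    4. ``lincRNA``    -- no span overlap with any coding locus.
    """
    candidates = [
        c
        for c in coding_ref.on_chromosome(t.chrom)
        if not (c.end <= t.start or c.start >= t.end)
    ]
    if not candidates:
        return "lincRNA"
    for c in candidates:
        if exonic_overlap(t, c, strand_mode="opposite") > 0:
            return "antisense"
    span = t.span
    for c in candidates:
        for intron in c.introns:
            if intron.start <= span.start and span.end <= intron.end:
                return "intronic"
    # fallback: per-exon intron containment within one coding transcript
    for c in candidates:
        if all(
            any(i.start <= e.start and e.end <= i.end for i in c.introns)
            for e in t.exons
        ):
            return "intronic"
    return "lincRNA"


def build_catalog(
    assembled: AnnotationSet,
    coding_ref: AnnotationSet,
    lnc_ref: AnnotationSet,
    expr: ExpressionMatrix,
    scores: Mapping[str, float] | None = None,
    params: FilterParams = FilterParams(),
    sequences: Mapping[str, str] | None = None,
) -> tuple[list[CatalogEntry], dict[str, int]]:
    """Filter, split and classify in one pass; returns (catalog, attrition)."""
    res = filter_candidates(
        assembled, coding_ref, expr, scores=scores, params=params,
        lnc_ref=lnc_ref, sequences=sequences,
    )
    novelty = split_known_novel(res.survivors, lnc_ref)
    catalog = [
        CatalogEntry(
            transcript=t,
            novelty=novelty[t.transcript_id],
            positional_class=classify_lncrna(t, coding_ref),
            coding_score=(
                float(scores[t.transcript_id])
                if scores is not None and t.transcript_id in scores
                else float("nan")
            ),
        )
        for t in res.survivors
    ]
    return catalog, res.attrition


def catalog_stats(
    catalog: Sequence[CatalogEntry], expr: ExpressionMatrix
) -> CatalogStats:
    """Exact size/splicing/expression summary of a catalog.

    Expression is summarised as the per-transcript mean of log10(FPKM + 1)
    across samples.
    """
    if not catalog:
        raise ValueError("catalog_stats: empty catalog")
    ts = [e.transcript for e in catalog]
    loci = {t.locus_id for t in ts}
    ids = [t.transcript_id for t in ts]
    logged = log_transform(expr.subset(ids), pseudocount=1.0, base=10.0)
    counts: dict[tuple[str, str], int] = {}
    for e in catalog:
        key = (e.novelty, e.positional_class)
        counts[key] = counts.get(key, 0) + 1
    return CatalogStats(
        n_transcripts=len(ts),
        n_loci=len(loci),
        mean_length=float(np.mean([t.length for t in ts])),
        mean_exons=float(np.mean([t.n_exons for t in ts])),
        isoforms_per_locus=len(ts) / len(loci),
        class_counts=counts,
        mean_log10_fpkm=logged.mean(axis=1),
    )


def write_catalog(catalog: Sequence[CatalogEntry], path: str | Path) -> None:
    rows = [
        {
            "transcript_id": e.transcript.transcript_id,
            "locus_id": e.transcript.locus_id,
            "novelty": e.novelty,
            "positional_class": e.positional_class,
            "length": e.transcript.length,
            "n_exons": e.transcript.n_exons,
            "coding_score": e.coding_score,
        }
        for e in catalog
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_attrition(attrition: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"stage": list(attrition), "removed": list(attrition.values())}
    ).to_csv(path, sep="\t", index=False)
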