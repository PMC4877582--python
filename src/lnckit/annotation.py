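"""Transcript data model, GTF/BED I/O and strand-aware interval arithmetic.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open ``[start, end)``.  GTF files
are read and written in the format's native 1-based closed convention; BED
files are already 0-based half-open and pass through unchanged.

Distances between transcripts on different chromosomes are reported as the
sentinel :data:`UNREACHABLE` (``math.inf``), so threshold comparisons like
``distance <= window`` behave correctly without special-casing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "UNREACHABLE",
    "GenomicInterval",
    "TranscriptModel",
    "AnnotationSet",
    "GtfParseError",
    "BedParseError",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "genomic_distance",
    "exonic_overlap",
    "feature_overlap_summary",
]

#: Sentinel distance for transcript pairs on different chromosomes.
UNREACHABLE: float = math.inf


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the offending line."""


class BedParseError(ValueError):
    """Raised for a malformed BED line; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a chromosome strand.

    ``strand`` is one of ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlapping bases with ``other``, ignoring strand; 0 if disjoint."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """One spliced transcript: ordered exons on a single chromosome strand."""

    transcript_id: str
    locus_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "other"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"{self.transcript_id}: exons span chromosomes/strands")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        """Genomic span start (first exon start)."""
        return self.exons[0].start

    @property
    def end(self) -> int:
        """Genomic span end (last exon end)."""
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        """Spliced transcript length: sum of exon lengths."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Intervals between consecutive exons (empty for single-exon models)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    @property
    def intron_chain(self) -> tuple:
        """Hashable identity of the splice structure: chrom, strand, intron coords."""
        return (self.chrom, self.strand, tuple((i.start, i.end) for i in self.introns))


class AnnotationSet:
    """A collection of transcripts indexed by id, chromosome and locus."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self._by_id: dict[str, TranscriptModel] = {}
        self._by_chrom: dict[str, list[TranscriptModel]] = {}
        self._by_locus: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._by_id:
            raise ValueError(f"duplicate transcript_id: {t.transcript_id}")
        self._by_id[t.transcript_id] = t
        self._by_chrom.setdefault(t.chrom, []).append(t)
        self._by_locus.setdefault(t.locus_id, []).append(t)

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._by_id.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self._by_id[transcript_id]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self._by_id)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    @property
    def locus_ids(self) -> list[str]:
        return list(self._by_locus)

    def on_chromosome(self, chrom: str) -> list[TranscriptModel]:
        return list(self._by_chrom.get(chrom, ()))

    def in_locus(self, locus_id: str) -> list[TranscriptModel]:
        return list(self._by_locus.get(locus_id, ()))

    def locus_span(self, locus_id: str) -> GenomicInterval:
        """Union span of all transcripts of a locus (gene-level footprint)."""
        ts = self._by_locus[locus_id]
        start = min(t.start for t in ts)
        end = max(t.end for t in ts)
        return GenomicInterval(ts[0].chrom, start, end, ts[0].strand)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field9: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field9))


def read_gtf(path: str | Path) -> AnnotationSet:
    """Read exon features from a GTF file into an :class:`AnnotationSet`.

    Only ``exon`` features are used; each must carry ``transcript_id`` and
    ``gene_id`` attributes (optionally ``biotype``).  GTF 1-based closed
    coordinates are converted to internal 0-based half-open.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}  # transcript -> (gene_id, biotype)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-numeric coordinates"
                ) from exc
            if end1 < start1:
                raise GtfParseError(
                    f"{path}: line {lineno}: end {end1} < start {start1}"
                )
            attr = _parse_attributes(attrs)
            if "transcript_id" not in attr or "gene_id" not in attr:
                raise GtfParseError(
                    f"{path}: line {lineno}: exon lacks transcript_id/gene_id"
                )
            tid = attr["transcript_id"]
            exons.setdefault(tid, []).append(
                GenomicInterval(chrom, start1 - 1, end1, strand)
            )
            meta[tid] = (attr["gene_id"], attr.get("biotype", "other"))
    out = AnnotationSet()
    for tid, ex in exons.items():
        gene_id, biotype = meta[tid]
        out.add(TranscriptModel(tid, gene_id, tuple(ex), biotype))
    return out


def write_gtf(annotation: AnnotationSet, path: str | Path) -> None:
    """Write one exon feature per exon, 1-based closed, deterministically ordered."""
    ts = sorted(annotation, key=lambda t: (t.chrom, t.start, t.transcript_id))
    with open(path, "w") as fh:
        for t in ts:
            for e in t.exons:
                attrs = (
                    f'transcript_id "{t.transcript_id}"; '
                    f'gene_id "{t.locus_id}"; '
                    f'biotype "{t.biotype}";'
                )
                fh.write(
                    f"{t.chrom}\tlnckit\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals (0-based half-open, returned unchanged)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-numeric coordinates"
                ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            out.append(GenomicInterval(fields[0], start, end, strand))
    return out


def genomic_distance(a: TranscriptModel, b: TranscriptModel) -> float:
    """Gap in bases between the genomic spans of two transcripts.

    Returns 0 when the spans overlap or abut, and :data:`UNREACHABLE`
    (infinity) when the transcripts are on different chromosomes.  Symmetric.
    """
    if a.chrom != b.chrom:
        return UNREACHABLE
    return float(max(0, max(a.start, b.start) - min(a.end, b.end)))


def _strand_allows(a: TranscriptModel, b: TranscriptModel, strand_mode: str) -> bool:
    if strand_mode == "ignore":
        return True
    if strand_mode == "same":
        return a.strand == b.strand
    if strand_mode == "opposite":
        return (a.strand, b.strand) in (("+", "-"), ("-", "+"))
    raise ValueError(f"invalid strand_mode: {strand_mode!r}")


def exonic_overlap(
    a: TranscriptModel, b: TranscriptModel, strand_mode: str = "ignore"
) -> int:
    """Total overlapping bases between the exon sets of two transcripts.

    ``strand_mode``: ``same`` counts only same-strand pairs, ``opposite`` only
    pairs on definite opposite strands, ``ignore`` counts regardless.
    Returns 0 when chromosomes differ or strand_mode excludes the pair.
    """
    if a.chrom != b.chrom or not _strand_allows(a, b, strand_mode):
        return 0
    total = 0
    for ea in a.exons:
        if ea.end <= b.start or ea.start >= b.end:
            continue
        for eb in b.exons:
            total += max(0, min(ea.end, eb.end) - max(ea.start, eb.start))
    return total


def feature_overlap_summary(
    loci: Sequence[TranscriptModel], features: Sequence[GenomicInterval]
) -> float:
    """Fraction of loci whose genomic span intersects at least one feature.

    Mirrors chromatin-feature summaries (e.g. the share of lncRNA loci whose
    regions carry DNase I hypersensitive sites); each locus counts once no
    matter how many features it touches.  Unstranded features match either
    strand.
    """
    if not loci:
        raise ValueError("feature_overlap_summary: empty locus list")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    hit = 0
    for t in loci:
        span = t.span
        for f in by_chrom.get(t.chrom, ()):
            if span.overlap(f) > 0:
                hit += 1
                break
    return hit / len(loci)
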