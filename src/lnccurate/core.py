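"""Domain types and genomic interval arithmetic shared by every pipeline stage.

All coordinates are 0-based half-open internally; GTF's 1-based closed
convention is converted at the I/O boundary. Strand is one of ``"+"``,
``"-"`` or ``"."`` (unknown); unknown is a first-class value and is never
coerced — direction-unknown transcripts flow through every downstream table
as their own category.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

PLUS = "+"
MINUS = "-"
UNKNOWN = "."

STRANDS = (PLUS, MINUS, UNKNOWN)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = UNKNOWN

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript with source provenance.

    ``exons`` are sorted, pairwise disjoint intervals on one chromosome and
    strand; ``span`` covers their union; ``length`` is the summed exon
    length (the mature-transcript length used by all length filters and
    RPKM denominators).
    """

    transcript_id: str
    gene_id: str
    source: str
    exons: tuple[GenomicInterval, ...]

    SOURCES = ("flybase", "ucsc", "young", "brown", "novel")

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"{self.transcript_id}: exons must share chrom and strand"
            )
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def five_prime(self) -> int:
        """Coordinate of the 5'-most transcribed base (TSS).

        Requires a known strand: on ``+`` it is the span start, on ``-``
        the last base before the span end.
        """
        if self.strand == PLUS:
            return self.span.start
        if self.strand == MINUS:
            return self.span.end - 1
        raise ValueError(
            f"{self.transcript_id}: 5' end undefined for unknown strand"
        )

    def with_strand(self, strand: str) -> "TranscriptModel":
        exons = tuple(replace(e, strand=strand) for e in self.exons)
        return replace(self, exons=exons)

    def same_loci(self, other: "TranscriptModel") -> bool:
        """Identical chrom, strand, span and exon boundary chain."""
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and [(e.start, e.end) for e in self.exons]
            == [(e.start, e.end) for e in other.exons]
        )


@dataclass(frozen=True)
class GeneModel:
    """One gene: one or more transcript isoforms sharing chrom and strand."""

    gene_id: str
    biotype: str
    transcripts: tuple[TranscriptModel, ...]

    BIOTYPES = ("coding", "lncRNA", "rRNA", "other")

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene needs >=1 transcript")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"{self.gene_id}: transcripts must share chrom and strand"
            )
        if self.strand == UNKNOWN and self.biotype != "lncRNA":
            raise ValueError(
                f"{self.gene_id}: strand may be unknown only for lncRNA genes"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        """Gene span: min start to max end over all isoforms."""
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def exons(self) -> tuple[GenomicInterval, ...]:
        out: list[GenomicInterval] = []
        for t in self.transcripts:
            out.extend(t.exons)
        return tuple(sorted(out, key=lambda e: (e.start, e.end)))

    @property
    def tss(self) -> int:
        """Gene-level TSS: 5'-most isoform start on the gene's strand."""
        if self.strand == PLUS:
            return self.span.start
        if self.strand == MINUS:
            return self.span.end - 1
        raise ValueError(f"{self.gene_id}: TSS undefined for unknown strand")


@dataclass
class ThresholdConfig:
    """Every tunable cutoff of the pipeline, with its published default.

    Lengths are bp, e-values dimensionless ceilings, identities percent,
    expression values RPKM, qPCR cutoffs cycles (−ΔCt).
    """

    min_lnc_length: int = 200
    rpkm_expressed: float = 1.0
    dedup_evalue: float = 1e-10
    dedup_overlap_default: float = 0.5
    dedup_overlap_young_vs_brown: float = 0.9
    rrna_evalue: float = 1e-10
    rrna_identity: float = 99.0
    coding_prob_cutoff: float = 0.39
    promoter_upstream: int = 500
    promoter_downstream: int = 100
    cage_window: int = 50
    trim_head: int = 10
    trim_quality: int = 20
    trim_min_len: int = 36
    qpcr_cutoff_brain: float = 1.0
    qpcr_cutoff_body: float = 2.0
    rpkm_q1: float = 2.78
    rpkm_q3: float = 12.92

    def __post_init__(self) -> None:
        for name in (
            "min_lnc_length",
            "rpkm_expressed",
            "dedup_overlap_default",
            "dedup_overlap_young_vs_brown",
            "promoter_upstream",
            "promoter_downstream",
            "cage_window",
            "trim_min_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.rpkm_q1 < self.rpkm_q3:
            raise ValueError("rpkm_q1 must be below rpkm_q3")


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two intervals; 0 across chromosomes. Strand
    is ignored."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def union_length(intervals: Sequence[GenomicInterval]) -> int:
    """Total bases covered by the union of intervals on one chromosome."""
    if not intervals:
        return 0
    if len({iv.chrom for iv in intervals}) != 1:
        raise ValueError("union_length requires intervals on one chromosome")
    total = 0
    cur_start = cur_end = None
    for iv in sorted(intervals, key=lambda x: x.start):
        if cur_end is None or iv.start > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = iv.start, iv.end
        else:
            cur_end = max(cur_end, iv.end)
    total += cur_end - cur_start
    return total


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals into a disjoint sorted list.

    Strand is dropped (merged intervals are unstranded coverage tracks).
    """
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        cur_start = cur_end = None
        for iv in sorted(by_chrom[chrom], key=lambda x: x.start):
            if cur_end is None or iv.start > cur_end:
                if cur_end is not None:
                    out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
            else:
                cur_end = max(cur_end, iv.end)
        if cur_end is not None:
            out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def intersect_length(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> int:
    """Bases in the intersection of two interval unions (strand-blind)."""
    total = 0
    b = list(b)
    for x in merge_intervals(a):
        pieces = []
        for y in b:
            if x.chrom != y.chrom:
                continue
            s, e = max(x.start, y.start), min(x.end, y.end)
            if s < e:
                pieces.append(GenomicInterval(x.chrom, s, e))
        if pieces:
            total += union_length(pieces)
    return total


def coverage_fraction(
    region: Sequence[GenomicInterval], peaks: Sequence[GenomicInterval]
) -> float:
    """Fraction of the region's union covered by the peaks' union.

    Peaks are clipped to the region; strand is ignored on both sides.
    """
    if not region:
        raise ValueError("coverage_fraction requires a non-empty region")
    denom = union_length(list(region))
    if not peaks:
        return 0.0
    return intersect_length(region, peaks) / denom
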