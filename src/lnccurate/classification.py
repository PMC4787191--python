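"""Positional classification of lncRNAs relative to protein-coding genes.

Each lncRNA transcript is placed in one of three location classes —
exonic-overlapping, intronic (contained in a coding gene's span without
exon contact), or intergenic — and the overlapping classes are split into
sense/antisense by strand agreement with the anchoring coding gene.
Transcripts whose transcriptional direction could not be determined go to
the ``unknown`` class regardless of location, since sense/antisense is
undefined for them.

Precedence when a transcript touches several genes: exon contact beats
intron containment beats intergenic; the anchor gene is the one with
maximal overlap (ties broken by gene id) for determinism.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import (
    GeneModel,
    TranscriptModel,
    UNKNOWN,
    intersect_length,
    overlap_length,
)

LNC_CLASSES = (
    "intergenic",
    "exonic_sense",
    "exonic_antisense",
    "intronic_sense",
    "intronic_antisense",
    "unknown",
)


@dataclass(frozen=True)
class ClassificationResult:
    transcript_id: str
    lnc_class: str
    anchor_gene_id: str | None
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.lnc_class not in LNC_CLASSES:
            raise ValueError(f"unknown class {self.lnc_class!r}")
        if self.overlap_bp < 0:
            raise ValueError("overlap_bp must be >= 0")


def _sense(lnc_strand: str, gene_strand: str) -> str:
    return "sense" if lnc_strand == gene_strand else "antisense"


def classify_transcript(
    lnc: TranscriptModel, coding_genes: Sequence[GeneModel]
) -> ClassificationResult:
    """Classify one lncRNA against a set of coding gene models.

    Exonic: any lnc exon overlaps any exon of the gene (overlap measured
    in exon-union bp). Intronic: the lnc span overlaps the gene span with
    no exon contact. Intergenic: no gene-span overlap at all. Coding genes
    must have a known strand; a direction-unknown lncRNA is classed
    ``unknown`` (its best overlap is still reported).
    """
    for g in coding_genes:
        if g.strand == UNKNOWN:
            raise ValueError(f"coding gene {g.gene_id} has unknown strand")

    exonic_hits: list[tuple[int, str, GeneModel]] = []
    span_hits: list[tuple[int, str, GeneModel]] = []
    for g in coding_genes:
        if g.chrom != lnc.chrom:
            continue
        exon_bp = intersect_length(lnc.exons, g.exons)
        if exon_bp > 0:
            exonic_hits.append((exon_bp, g.gene_id, g))
        span_bp = overlap_length(lnc.span, g.span)
        if span_bp > 0:
            span_hits.append((span_bp, g.gene_id, g))

    def best(hits: list[tuple[int, str, GeneModel]]) -> tuple[int, GeneModel]:
        bp, _gid, gene = max(hits, key=lambda h: (h[0], _NegStr(h[1])))
        return bp, gene

    if lnc.strand == UNKNOWN:
        if exonic_hits:
            bp, gene = best(exonic_hits)
            return ClassificationResult(
                lnc.transcript_id, "unknown", gene.gene_id, bp
            )
        if span_hits:
            bp, gene = best(span_hits)
            return ClassificationResult(
                lnc.transcript_id, "unknown", gene.gene_id, bp
            )
        return ClassificationResult(lnc.transcript_id, "unknown", None, 0)

    if exonic_hits:
        bp, gene = best(exonic_hits)
        return ClassificationResult(
            lnc.transcript_id,
            f"exonic_{_sense(lnc.strand, gene.strand)}",
            gene.gene_id,
            bp,
        )
    if span_hits:
        bp, gene = best(span_hits)
        return ClassificationResult(
            lnc.transcript_id,
            f"intronic_{_sense(lnc.strand, gene.strand)}",
            gene.gene_id,
            bp,
        )
    return ClassificationResult(lnc.transcript_id, "intergenic", None, 0)


class _NegStr:
    """Orders strings reversed, so max() picks the lexicographically
    smallest gene id on overlap ties."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _NegStr) and self.s == other.s


def classify_all(
    lncs: Iterable[TranscriptModel], coding_genes: Sequence[GeneModel]
) -> list[ClassificationResult]:
    return [classify_transcript(t, coding_genes) for t in lncs]


def assign_direction(
    lnc_id: str, stranded_calls: Sequence[str]
) -> str:
    """Consolidate strand calls from stranded assemblies for one lncRNA.

    Unanimous non-unknown calls fix the direction; conflicting or absent
    calls leave it unknown.
    """
    calls = {c for c in stranded_calls if c != UNKNOWN}
    if len(calls) == 1:
        return calls.pop()
    return UNKNOWN


def summarize_exon_counts(
    transcripts: Sequence[TranscriptModel],
) -> dict[int, tuple[int, float]]:
    """Histogram of exon counts: {exon_count: (n_transcripts, fraction)}."""
    if not transcripts:
        raise ValueError("cannot summarize an empty transcript set")
    counts = Counter(t.exon_count for t in transcripts)
    total = len(transcripts)
    return {k: (n, n / total) for k, n in sorted(counts.items())}
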