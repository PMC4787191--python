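"""Chromatin-signature assignment and CAGE 5'-completeness.

Three marks are assessed per gene against pooled peak tracks (all datasets
of one mark are unioned — any-stage presence counts):

* H3K4me3 — present if any peak touches the promoter window, 500 bp
  upstream to 100 bp downstream of the gene-level TSS in transcription
  direction (601 bp unless clipped at the chromosome start).
* H3K36me3 — fraction of the transcribed region (gene span TSS to TES,
  introns included) covered by the peak union; present if any coverage.
* Pol II — present if any peak touches promoter or transcribed region;
  coverage reported over the transcribed region only.

The K4–K36 signature is the conjunction of the first two. CAGE
5'-completeness asks for a peak within +/-50 bp (inclusive) of a
transcript's 5' base. Expressed genes are binned into validation groups
G1–G4 by crossing all-three/none-of-three signatures with high/low
expression quartile cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import (
    GeneModel,
    GenomicInterval,
    MINUS,
    PLUS,
    ThresholdConfig,
    TranscriptModel,
    UNKNOWN,
    coverage_fraction,
    overlap_length,
)
from .io import PeakRecord


@dataclass(frozen=True)
class ChromatinAnnotation:
    gene_id: str
    h3k4me3_present: bool | None  # None = not assessable (unknown strand)
    h3k36me3_coverage: float
    h3k36me3_present: bool
    polII_present: bool
    polII_coverage: float

    def __post_init__(self) -> None:
        for c in (self.h3k36me3_coverage, self.polII_coverage):
            if not 0 <= c <= 1:
                raise ValueError("coverage must be in [0, 1]")

    @property
    def k4k36(self) -> bool:
        return bool(self.h3k4me3_present) and self.h3k36me3_present

    @property
    def all_three(self) -> bool:
        return self.k4k36 and self.polII_present

    @property
    def none_of_three(self) -> bool:
        # an unassessable promoter (unknown strand) is not an assessed
        # absence, so such genes belong to neither signature group
        return (
            self.h3k4me3_present is False
            and not self.h3k36me3_present
            and not self.polII_present
        )


@dataclass(frozen=True)
class ValidationGroup:
    gene_id: str
    group: str  # G1 | G2 | G3 | G4 | none

    def __post_init__(self) -> None:
        if self.group not in ("G1", "G2", "G3", "G4", "none"):
            raise ValueError(f"unknown group {self.group!r}")


def promoter_window(
    tss: int,
    strand: str,
    chrom: str,
    thresholds: ThresholdConfig | None = None,
) -> GenomicInterval:
    """Promoter interval around a TSS in transcription direction.

    Covers signed distances −upstream..+downstream from the TSS base
    inclusive; clipped at the chromosome start.
    """
    t = thresholds or ThresholdConfig()
    if strand == PLUS:
        start = tss - t.promoter_upstream
        end = tss + t.promoter_downstream + 1
    elif strand == MINUS:
        start = tss - t.promoter_downstream
        end = tss + t.promoter_upstream + 1
    else:
        raise ValueError("promoter window undefined for unknown strand")
    return GenomicInterval(chrom, max(0, start), end, strand)


def _peaks_of(peaks: Sequence[PeakRecord], mark: str) -> list[GenomicInterval]:
    return [p.interval for p in peaks if p.mark == mark]


def assign_h3k4me3(
    gene: GeneModel,
    peaks: Sequence[PeakRecord],
    thresholds: ThresholdConfig | None = None,
) -> bool | None:
    """Promoter H3K4me3 presence; None when the gene's strand is unknown
    (not assessable — distinct from an assessed absence)."""
    if gene.strand == UNKNOWN:
        return None
    window = promoter_window(gene.tss, gene.strand, gene.chrom, thresholds)
    return any(
        overlap_length(window, iv) > 0 for iv in _peaks_of(peaks, "H3K4me3")
    )


def assign_h3k36me3(
    gene: GeneModel, peaks: Sequence[PeakRecord]
) -> tuple[bool, float]:
    """(present, coverage) of the transcribed region by H3K36me3 peaks."""
    cov = coverage_fraction([gene.span], _peaks_of(peaks, "H3K36me3"))
    return cov > 0, cov


def assign_polII(
    gene: GeneModel,
    peaks: Sequence[PeakRecord],
    thresholds: ThresholdConfig | None = None,
) -> tuple[bool, float]:
    """Pol II occupancy over promoter + transcribed region.

    Presence considers both regions (promoter omitted for unknown-strand
    genes); coverage is over the transcribed region only, so a
    promoter-only signal yields (True, 0.0).
    """
    pol = _peaks_of(peaks, "PolII")
    regions = [gene.span]
    if gene.strand != UNKNOWN:
        regions.append(
            promoter_window(gene.tss, gene.strand, gene.chrom, thresholds)
        )
    present = any(
        overlap_length(region, iv) > 0 for region in regions for iv in pol
    )
    coverage = coverage_fraction([gene.span], pol)
    return present, coverage


def k4k36_call(annotation: ChromatinAnnotation) -> bool:
    """The joint promoter-K4 / body-K36 signature of active transcription."""
    return annotation.k4k36


def annotate_gene(
    gene: GeneModel,
    peaks: Sequence[PeakRecord],
    thresholds: ThresholdConfig | None = None,
) -> ChromatinAnnotation:
    k4 = assign_h3k4me3(gene, peaks, thresholds)
    k36_present, k36_cov = assign_h3k36me3(gene, peaks)
    pol_present, pol_cov = assign_polII(gene, peaks, thresholds)
    return ChromatinAnnotation(
        gene_id=gene.gene_id,
        h3k4me3_present=k4,
        h3k36me3_coverage=k36_cov,
        h3k36me3_present=k36_present,
        polII_present=pol_present,
        polII_coverage=pol_cov,
    )


def cage_complete(
    transcript: TranscriptModel,
    cage_peaks: Sequence[PeakRecord],
    thresholds: ThresholdConfig | None = None,
) -> bool | None:
    """True if a CAGE peak falls within +/-window bp (inclusive) of the
    transcript's 5' base; None when the strand is unknown."""
    t = thresholds or ThresholdConfig()
    if transcript.strand == UNKNOWN:
        return None
    five = transcript.five_prime
    window = GenomicInterval(
        transcript.chrom,
        max(0, five - t.cage_window),
        five + t.cage_window + 1,
    )
    return any(
        overlap_length(window, iv) > 0 for iv in _peaks_of(cage_peaks, "CAGE")
    )


def assign_validation_group(
    rpkm: float,
    annotation: ChromatinAnnotation,
    thresholds: ThresholdConfig | None = None,
) -> ValidationGroup:
    """Cross signature status with expression quartiles for an expressed
    gene. Genes between the quartiles, or with a partial signature set,
    fall in no group."""
    t = thresholds or ThresholdConfig()
    if rpkm <= t.rpkm_expressed:
        raise ValueError(
            "validation groups are defined for expressed genes only "
            f"(rpkm {rpkm} <= {t.rpkm_expressed})"
        )
    high = rpkm > t.rpkm_q3
    low = rpkm < t.rpkm_q1
    if annotation.all_three and high:
        group = "G1"
    elif annotation.all_three and low:
        group = "G2"
    elif annotation.none_of_three and high:
        group = "G3"
    elif annotation.none_of_three and low:
        group = "G4"
    else:
        group = "none"
    return ValidationGroup(annotation.gene_id, group)
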