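"""The novel-lncRNA filter funnel.

Assembled transcripts from the two brain libraries (poly(A)-enriched and
ribo-zero) are reduced to a union set of intergenic candidates, then
pushed through an ordered chain of filters — minimum length, coding
potential, ribosomal-RNA exclusion, read support on remapping, and
sense-strand overlap with newly annotated coding genes — with per-stage
in/removed/out accounting.

Intergenicity is strand-blind: exon overlap with any annotated transcript
on either strand disqualifies a candidate. The sense-overlap filter, by
contrast, tests exon–exon overlap on the same strand only, so an
antisense or intron-contained transcript survives it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .core import (
    ThresholdConfig,
    TranscriptModel,
    UNKNOWN,
)
from .curation import exclude_rrna, filter_min_length
from .io import AlignmentRecord, CodingPotentialRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FunnelStage:
    """One filter stage's accounting: in, removed, out."""

    name: str
    count_in: int
    removed: int
    count_out: int

    def __post_init__(self) -> None:
        if self.removed < 0:
            raise ValueError(f"{self.name}: removed must be >= 0")
        if self.count_out != self.count_in - self.removed:
            raise ValueError(
                f"{self.name}: count_out {self.count_out} != "
                f"{self.count_in} - {self.removed}"
            )


@dataclass
class FunnelReport:
    """Ordered stages of one funnel run."""

    stages: list[FunnelStage]

    @property
    def final_count(self) -> int:
        return self.stages[-1].count_out if self.stages else 0

    def to_rows(self) -> list[tuple[str, int, int, int]]:
        return [
            (s.name, s.count_in, s.removed, s.count_out) for s in self.stages
        ]


def _span_tree(transcripts: Sequence[TranscriptModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for t in transcripts:
        sp = t.span
        trees.setdefault(sp.chrom, IntervalTree()).addi(sp.start, sp.end, t)
    return trees


def _exon_tree(transcripts: Sequence[TranscriptModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for t in transcripts:
        for e in t.exons:
            trees.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, t)
    return trees


def find_intergenic_candidates(
    assembled: Sequence[TranscriptModel] | Sequence[Sequence[TranscriptModel]],
    reference: Sequence[TranscriptModel],
) -> list[TranscriptModel]:
    """Union the assembled libraries and keep transcripts whose exons touch
    no reference transcript span on either strand.

    ``assembled`` may be one flat list or one list per library; exact
    structural duplicates across libraries collapse to one candidate.
    """
    if assembled and isinstance(assembled[0], TranscriptModel):
        libraries = [list(assembled)]  # type: ignore[list-item]
    else:
        libraries = [list(lib) for lib in assembled]  # type: ignore[union-attr]

    ref_trees = _span_tree(reference)
    seen_loci: set[tuple] = set()
    candidates: list[TranscriptModel] = []
    for library in libraries:
        for t in library:
            key = (
                t.chrom,
                t.strand,
                tuple((e.start, e.end) for e in t.exons),
            )
            if key in seen_loci:
                continue
            seen_loci.add(key)
            tree = ref_trees.get(t.chrom)
            if tree is not None and any(
                tree.overlap(e.start, e.end) for e in t.exons
            ):
                continue
            candidates.append(t)
    return candidates


def filter_coding_potential(
    candidates: Sequence[TranscriptModel],
    scores: Sequence[CodingPotentialRecord],
    cutoff: float,
) -> tuple[list[TranscriptModel], list[str]]:
    """Keep candidates assessed non-coding.

    SVM labels keep only "noncoding"; probability scores keep strictly
    below the cutoff (a probability at the cutoff is treated as coding).
    Every candidate must have a score record.
    """
    by_id: dict[str, CodingPotentialRecord] = {}
    for s in scores:
        by_id.setdefault(s.transcript_id, s)
    missing = [
        t.transcript_id for t in candidates if t.transcript_id not in by_id
    ]
    if missing:
        raise ValueError(
            f"missing coding-potential scores for: {', '.join(missing)}"
        )
    kept, removed = [], []
    for t in candidates:
        rec = by_id[t.transcript_id]
        if rec.method == "cpc_label":
            noncoding = rec.value == "noncoding"
        else:
            noncoding = float(rec.value) < cutoff
        if noncoding:
            kept.append(t)
        else:
            removed.append(t.transcript_id)
    return kept, removed


def filter_read_support(
    candidates: Sequence[TranscriptModel],
    remap_counts: Mapping[str, int],
) -> tuple[list[TranscriptModel], list[str]]:
    """Keep candidates with at least one supporting read on remapping;
    an id absent from the count map is unsupported."""
    kept, removed = [], []
    for t in candidates:
        if remap_counts.get(t.transcript_id, 0) > 0:
            kept.append(t)
        else:
            removed.append(t.transcript_id)
    return kept, removed


def filter_sense_overlap(
    candidates: Sequence[TranscriptModel],
    updated_annotation: Sequence[TranscriptModel],
) -> tuple[list[TranscriptModel], list[str]]:
    """Remove candidates whose exons overlap a coding transcript's exons on
    the same strand. Unknown-strand candidates cannot be assessed and are
    kept with a warning."""
    exon_trees = _exon_tree(updated_annotation)
    kept, removed = [], []
    for t in candidates:
        if t.strand == UNKNOWN:
            logger.warning(
                "%s: unknown strand, sense-overlap not assessable; kept",
                t.transcript_id,
            )
            kept.append(t)
            continue
        tree = exon_trees.get(t.chrom)
        hit = False
        if tree is not None:
            for e in t.exons:
                if any(
                    iv.data.strand == t.strand
                    for iv in tree.overlap(e.start, e.end)
                ):
                    hit = True
                    break
        if hit:
            removed.append(t.transcript_id)
        else:
            kept.append(t)
    return kept, removed


def run_discovery_funnel(
    assembled: Sequence[TranscriptModel] | Sequence[Sequence[TranscriptModel]],
    reference: Sequence[TranscriptModel],
    scores: Sequence[CodingPotentialRecord],
    rrna_alignments: Sequence[AlignmentRecord],
    remap_counts: Mapping[str, int],
    updated_annotation: Sequence[TranscriptModel],
    thresholds: ThresholdConfig | None = None,
) -> tuple[list[TranscriptModel], FunnelReport]:
    """Run the full funnel in its fixed order and account every stage.

    Order: intergenic detection -> length -> coding potential -> rRNA ->
    read support -> sense overlap. Stage 1's count_in is the union-set
    size before intergenic screening.
    """
    thresholds = thresholds or ThresholdConfig()
    stages: list[FunnelStage] = []

    if assembled and isinstance(assembled[0], TranscriptModel):
        n_union = len(
            {
                (t.chrom, t.strand, tuple((e.start, e.end) for e in t.exons))
                for t in assembled  # type: ignore[union-attr]
            }
        )
    else:
        n_union = len(
            {
                (t.chrom, t.strand, tuple((e.start, e.end) for e in t.exons))
                for lib in assembled
                for t in lib
            }
        )
    current = find_intergenic_candidates(assembled, reference)
    stages.append(
        FunnelStage("intergenic", n_union, n_union - len(current), len(current))
    )

    n_in = len(current)
    current, _ = filter_min_length(current, thresholds.min_lnc_length)
    stages.append(FunnelStage("length", n_in, n_in - len(current), len(current)))

    n_in = len(current)
    current, removed_ids = filter_coding_potential(
        current, scores, thresholds.coding_prob_cutoff
    )
    stages.append(
        FunnelStage("coding_potential", n_in, len(removed_ids), len(current))
    )

    n_in = len(current)
    current, _ = exclude_rrna(current, rrna_alignments, thresholds)
    stages.append(
        FunnelStage("rrna", n_in, n_in - len(current), len(current))
    )

    n_in = len(current)
    current, removed_ids = filter_read_support(current, remap_counts)
    stages.append(
        FunnelStage("read_support", n_in, len(removed_ids), len(current))
    )

    n_in = len(current)
    current, removed_ids = filter_sense_overlap(current, updated_annotation)
    stages.append(
        FunnelStage("sense_overlap", n_in, len(removed_ids), len(current))
    )

    return current, FunnelReport(stages)
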