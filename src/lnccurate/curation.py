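"""Merging lncRNA sets from multiple sources into a non-redundant list.

Candidates from each successive source are screened against the already
accepted ("primary") set with source-specific redundancy rules:

* ``flybase_ucsc`` — drop a candidate that shares its loci with, or whose
  alignment covers >= 50 % of its own length against, any primary
  transcript.
* ``brown`` — drop a candidate already carrying an accepted FlyBase ID,
  or whose alignment covers > 50 % of either transcript's length — unless
  the candidate is multi-exon and its exon count differs from the matched
  primary transcript's (structurally distinct isoforms are retained).
* ``young_vs_brown`` — drop only on identical loci or >= 90 % coverage of
  the candidate's length.

Only alignments below the configured E-value ceiling are evidence. When no
alignment records are supplied, a genome-coordinate fallback derives the
same quantities from exon-union intersections (flagged in the decisions).

Ribosomal contamination is excluded on joint E-value/identity thresholds,
and transcripts whose current annotation status falls in a removal
vocabulary (protein coding, pseudogene, structural RNA classes, stale or
dropped IDs, transposon regions) are filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import ThresholdConfig, TranscriptModel, intersect_length
from .io import AlignmentRecord

REMOVAL_STATUSES = frozenset(
    {
        "protein_coding",
        "pseudogene",
        "rRNA",
        "snRNA",
        "snoRNA",
        "scaRNA",
        "out_of_date",
        "TE_region",
        "dropped_sequence",
    }
)

REASONS = (
    "kept",
    "too_short",
    "same_loci",
    "overlap_50",
    "overlap_90",
    "flybase_id_duplicate",
    "rrna_contamination",
    "status_removed",
)

DEDUP_RULES = ("flybase_ucsc", "brown", "young_vs_brown")


@dataclass(frozen=True)
class CurationDecision:
    """The fate of one input transcript, with the rule that decided it."""

    transcript_id: str
    kept: bool
    reason: str
    evidence_id: str = ""
    provenance: str = "alignment"

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if self.kept != (self.reason == "kept"):
            raise ValueError("reason must be 'kept' iff kept is true")


def filter_min_length(
    transcripts: Sequence[TranscriptModel], min_len: int
) -> tuple[list[TranscriptModel], list[CurationDecision]]:
    """Keep transcripts of at least ``min_len`` mature length.

    The boundary is kept: only strictly shorter transcripts are removed.
    """
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    kept, decisions = [], []
    for t in transcripts:
        if t.length >= min_len:
            kept.append(t)
            decisions.append(CurationDecision(t.transcript_id, True, "kept"))
        else:
            decisions.append(
                CurationDecision(t.transcript_id, False, "too_short")
            )
    return kept, decisions


def _coordinate_fallback_alignments(
    candidates: Sequence[TranscriptModel],
    primary: Sequence[TranscriptModel],
) -> list[AlignmentRecord]:
    """Derive alignment-like evidence from genomic exon-union overlaps.

    E-values are set to 0 so every derived record passes the ceiling;
    same_loci is computed structurally.
    """
    records = []
    for c in candidates:
        for p in primary:
            shared = intersect_length(c.exons, p.exons)
            if shared == 0 and not c.same_loci(p):
                continue
            records.append(
                AlignmentRecord(
                    query_id=c.transcript_id,
                    subject_id=p.transcript_id,
                    e_value=0.0,
                    identity_pct=100.0,
                    overlap_fraction_query=min(1.0, shared / c.length),
                    overlap_fraction_subject=min(1.0, shared / p.length),
                    same_loci=c.same_loci(p),
                )
            )
    return records


def dedup_against_primary(
    candidates: Sequence[TranscriptModel],
    primary_set: Sequence[TranscriptModel],
    alignments: Sequence[AlignmentRecord] | None,
    rule: str,
    thresholds: ThresholdConfig | None = None,
    flybase_id_map: Mapping[str, str] | None = None,
) -> tuple[list[TranscriptModel], list[CurationDecision]]:
    """Screen candidates against an accepted primary set under one rule.

    ``flybase_id_map`` (candidate id -> FlyBase ID annotated in its source
    file) feeds the brown rule's ID-duplicate check. Candidates are judged
    independently against the full primary set, so input order never
    affects the outcome and re-running the survivors removes nothing.
    """
    if rule not in DEDUP_RULES:
        raise ValueError(f"unknown dedup rule {rule!r}")
    thresholds = thresholds or ThresholdConfig()
    provenance = "alignment"
    if alignments is None:
        alignments = _coordinate_fallback_alignments(candidates, primary_set)
        provenance = "coordinate_fallback"

    candidate_ids = {t.transcript_id for t in candidates}
    known_ids = candidate_ids | {t.transcript_id for t in primary_set}
    primary_by_id = {t.transcript_id: t for t in primary_set}
    by_query: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        if a.subject_id not in known_ids:
            raise ValueError(
                f"alignment references absent transcript {a.subject_id!r}"
            )
        # alignments whose query is outside the candidate set carry no
        # evidence here (e.g. re-running dedup on an already-kept subset)
        if a.query_id not in candidate_ids:
            continue
        if a.e_value < thresholds.dedup_evalue:
            by_query.setdefault(a.query_id, []).append(a)

    primary_ids = set(primary_by_id)
    flybase_id_map = flybase_id_map or {}
    kept, decisions = [], []
    for cand in candidates:
        verdict: tuple[str, str] | None = None  # (reason, evidence)
        if rule == "brown":
            fb_id = flybase_id_map.get(cand.transcript_id)
            if fb_id is not None and fb_id in primary_ids:
                verdict = ("flybase_id_duplicate", fb_id)
        if verdict is None:
            for aln in by_query.get(cand.transcript_id, []):
                if aln.subject_id not in primary_ids:
                    continue
                subj = primary_by_id[aln.subject_id]
                if rule == "flybase_ucsc":
                    if aln.same_loci:
                        verdict = ("same_loci", subj.transcript_id)
                    elif (
                        aln.overlap_fraction_query
                        >= thresholds.dedup_overlap_default
                    ):
                        verdict = ("overlap_50", subj.transcript_id)
                elif rule == "brown":
                    frac = max(
                        aln.overlap_fraction_query,
                        aln.overlap_fraction_subject,
                    )
                    if frac > thresholds.dedup_overlap_default:
                        exempt = (
                            cand.exon_count >= 2
                            and cand.exon_count != subj.exon_count
                        )
                        if not exempt:
                            verdict = ("overlap_50", subj.transcript_id)
                else:  # young_vs_brown
                    if aln.same_loci:
                        verdict = ("same_loci", subj.transcript_id)
                    elif (
                        aln.overlap_fraction_query
                        >= thresholds.dedup_overlap_young_vs_brown
                    ):
                        verdict = ("overlap_90", subj.transcript_id)
                if verdict is not None:
                    break
        if verdict is None:
            kept.append(cand)
            decisions.append(
                CurationDecision(
                    cand.transcript_id, True, "kept", provenance=provenance
                )
            )
        else:
            reason, evidence = verdict
            decisions.append(
                CurationDecision(
                    cand.transcript_id,
                    False,
                    reason,
                    evidence_id=evidence,
                    provenance=provenance,
                )
            )
    return kept, decisions


def exclude_rrna(
    transcripts: Sequence[TranscriptModel],
    rrna_alignments: Sequence[AlignmentRecord],
    thresholds: ThresholdConfig | None = None,
) -> tuple[list[TranscriptModel], list[CurationDecision]]:
    """Remove transcripts aligning to a ribosomal RNA below the E-value
    ceiling with identity above the floor (both must hold)."""
    thresholds = thresholds or ThresholdConfig()
    hits: dict[str, str] = {}
    for a in rrna_alignments:
        if (
            a.e_value < thresholds.rrna_evalue
            and a.identity_pct > thresholds.rrna_identity
        ):
            hits.setdefault(a.query_id, a.subject_id)
    kept, decisions = [], []
    for t in transcripts:
        if t.transcript_id in hits:
            decisions.append(
                CurationDecision(
                    t.transcript_id,
                    False,
                    "rrna_contamination",
                    evidence_id=hits[t.transcript_id],
                )
            )
        else:
            kept.append(t)
            decisions.append(CurationDecision(t.transcript_id, True, "kept"))
    return kept, decisions


def apply_status_filter(
    transcripts: Sequence[TranscriptModel],
    status_table: Mapping[str, str],
) -> tuple[list[TranscriptModel], list[CurationDecision]]:
    """Drop transcripts whose current annotation status disqualifies them.

    IDs absent from the table carry no evidence against them and are kept.
    """
    kept, decisions = [], []
    for t in transcripts:
        status = status_table.get(t.transcript_id)
        if status in REMOVAL_STATUSES:
            decisions.append(
                CurationDecision(
                    t.transcript_id,
                    False,
                    "status_removed",
                    evidence_id=status,
                )
            )
        else:
            kept.append(t)
            decisions.append(CurationDecision(t.transcript_id, True, "kept"))
    return kept, decisions


def overlap_groups(
    transcripts: Sequence[TranscriptModel],
) -> list[list[str]]:
    """Report groups of curated transcripts from different sources whose
    exons overlap on the genome (candidates for manual merging; the
    pipeline reports them and never merges)."""
    txs = list(transcripts)
    parent = list(range(len(txs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(txs):
        for j in range(i + 1, len(txs)):
            b = txs[j]
            if a.source != b.source and intersect_length(a.exons, b.exons):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, list[str]] = {}
    for i, t in enumerate(txs):
        groups.setdefault(find(i), []).append(t.transcript_id)
    return sorted(
        [sorted(g) for g in groups.values() if len(g) > 1],
        key=lambda g: g[0],
    )


def write_decisions(
    decisions: Iterable[CurationDecision],
    sources: Mapping[str, str],
    path,
) -> None:
    """Write a decisions TSV: id, source, kept, reason, evidence_id."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tsource\tkept\treason\tevidence_id\n")
        for d in decisions:
            fh.write(
                f"{d.transcript_id}\t{sources.get(d.transcript_id, '')}\t"
                f"{int(d.kept)}\t{d.reason}\t{d.evidence_id}\n"
            )
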