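"""Readers and writers for the flat formats the pipeline touches.

GTF exon features (1-based closed, converted on read), BED3/BED6 peaks
(native 0-based half-open), 12-column BLAST-style tabular alignments with a
companion length table, coding-potential and status TSVs, and per-library
count tables with ``#total_mapped=`` headers.

Parsers are strict by default: a malformed record raises ``FormatError``
naming the line; ``lenient=True`` logs and skips instead. Both GTF
attribute dialects (``key "value";`` and ``key=value``) are accepted
because annotation sources mix them. Transcript spans are always
recomputed from exons; span features in the file are ignored.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .core import (
    GenomicInterval,
    ThresholdConfig,
    TranscriptModel,
    UNKNOWN,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A malformed record in an input file."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise similarity report between two transcripts.

    Overlap fractions are the aligned length divided by each transcript's
    own length, capped at 1. ``same_loci`` flags structurally identical
    genomic models (same chrom, strand, span and exon chain).
    """

    query_id: str
    subject_id: str
    e_value: float
    identity_pct: float
    overlap_fraction_query: float
    overlap_fraction_subject: float
    same_loci: bool = False

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not 0 <= self.identity_pct <= 100:
            raise ValueError("identity_pct must be in [0, 100]")
        for f in (self.overlap_fraction_query, self.overlap_fraction_subject):
            if not 0 <= f <= 1:
                raise ValueError("overlap fractions must be in [0, 1]")


@dataclass(frozen=True)
class CodingPotentialRecord:
    """A coding-potential assessment: an SVM label or a logistic probability."""

    transcript_id: str
    method: str  # "cpc_label" | "cpat_probability"
    value: object  # "coding"/"noncoding" or float in [0, 1]

    def __post_init__(self) -> None:
        if self.method == "cpat_probability":
            if not 0 <= float(self.value) <= 1:
                raise ValueError("probability must be in [0, 1]")
        elif self.method == "cpc_label":
            if self.value not in ("coding", "noncoding"):
                raise ValueError(f"unknown label {self.value!r}")
        else:
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class PeakRecord:
    """One chromatin/CAGE peak interval tagged with mark and dataset."""

    interval: GenomicInterval
    mark: str  # H3K4me3 | H3K36me3 | PolII | CAGE
    dataset: str = ""


_ATTR_QUOTED = re.compile(r'(\w+)\s+"([^"]*)"')
_ATTR_EQ = re.compile(r"(\w+)=([^;]+)")


def _parse_attributes(text: str) -> dict[str, str]:
    attrs = dict(_ATTR_QUOTED.findall(text))
    for key, val in _ATTR_EQ.findall(text):
        attrs.setdefault(key, val.strip().strip('"'))
    return attrs


def read_transcripts(
    path: str | Path,
    source: str = "flybase",
    lenient: bool = False,
) -> list[TranscriptModel]:
    """Read exon features from a GTF into transcript models.

    1-based closed GTF coordinates become 0-based half-open; strand "."
    maps to unknown. One model is emitted per transcript_id, its span and
    length recomputed from the exon chain.
    """
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    gene_by_tx: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                msg = f"{path}:{lineno}: expected 9 tab-separated fields"
                if lenient:
                    logger.warning("skipping malformed line: %s", msg)
                    continue
                raise FormatError(msg)
            chrom, _src, feature, start, end, _score, strand, _frame, attr = (
                fields[:9]
            )
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                msg = f"{path}:{lineno}: non-integer coordinates"
                if lenient:
                    logger.warning("skipping malformed line: %s", msg)
                    continue
                raise FormatError(msg) from None
            attrs = _parse_attributes(attr)
            tx_id = attrs.get("transcript_id")
            if not tx_id:
                msg = f"{path}:{lineno}: exon without transcript_id"
                if lenient:
                    logger.warning("skipping malformed line: %s", msg)
                    continue
                raise FormatError(msg)
            if strand not in ("+", "-", "."):
                msg = f"{path}:{lineno}: invalid strand {strand!r}"
                if lenient:
                    logger.warning("skipping malformed line: %s", msg)
                    continue
                raise FormatError(msg)
            iv = GenomicInterval(
                chrom, start_i - 1, end_i, strand if strand != "." else UNKNOWN
            )
            if tx_id not in exons_by_tx:
                order.append(tx_id)
            exons_by_tx.setdefault(tx_id, []).append(iv)
            gene_by_tx.setdefault(tx_id, attrs.get("gene_id", tx_id))
    return [
        TranscriptModel(
            transcript_id=tx,
            gene_id=gene_by_tx[tx],
            source=source,
            exons=tuple(exons_by_tx[tx]),
        )
        for tx in order
    ]


def write_transcripts(
    transcripts: Iterable[TranscriptModel], path: str | Path
) -> None:
    """Write transcripts as GTF exon features (1-based closed)."""
    with open(path, "w") as fh:
        for t in transcripts:
            for exon in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                )
                fh.write(
                    "\t".join(
                        [
                            exon.chrom,
                            t.source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_peaks(
    path: str | Path, mark: str, dataset: str = ""
) -> list[PeakRecord]:
    """Read a BED3+ peak file, tagging every interval with mark/dataset.

    BED is natively 0-based half-open; a BED6 strand column is parsed but
    peak strand plays no role downstream.
    """
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            strand = fields[5] if len(fields) >= 6 else "."
            if strand not in ("+", "-", "."):
                strand = "."
            peaks.append(
                PeakRecord(
                    GenomicInterval(chrom, start, end, strand), mark, dataset
                )
            )
    return peaks


def write_peaks(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            name = p.dataset or p.mark
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


def read_length_table(path: str | Path) -> dict[str, int]:
    """Read a 2-column (id, length) TSV; a FASTA is accepted instead."""
    path = Path(path)
    lengths: dict[str, int] = {}
    with open(path) as fh:
        head = fh.read(1)
    if head == ">":
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            lengths[rec.id] = len(rec.seq)
        return lengths
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected id<TAB>length")
            lengths[fields[0]] = int(fields[1])
    return lengths


def read_alignments(
    path: str | Path, lengths: Mapping[str, int]
) -> list[AlignmentRecord]:
    """Read BLAST-style 12-column tabular alignments.

    Overlap fractions are aligned-length / transcript-length per side,
    capped at 1; transcript lengths come from the companion table because
    the tabular dialect omits them.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tabular columns"
                )
            query, subject = fields[0], fields[1]
            identity = float(fields[2])
            aln_len = int(fields[3])
            e_value = float(fields[10])
            for tid in (query, subject):
                if tid not in lengths:
                    raise FormatError(
                        f"{path}:{lineno}: unknown transcript id {tid!r} "
                        "in length lookup"
                    )
            records.append(
                AlignmentRecord(
                    query_id=query,
                    subject_id=subject,
                    e_value=e_value,
                    identity_pct=identity,
                    overlap_fraction_query=min(
                        1.0, aln_len / lengths[query]
                    ),
                    overlap_fraction_subject=min(
                        1.0, aln_len / lengths[subject]
                    ),
                )
            )
    return records


def read_coding_potential(path: str | Path) -> list[CodingPotentialRecord]:
    """Read a coding-potential TSV: transcript_id, method, value."""
    out: list[CodingPotentialRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "transcript_id":
                continue
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected id, method, value"
                )
            tid, method, raw = fields[:3]
            value = float(raw) if method == "cpat_probability" else raw
            out.append(CodingPotentialRecord(tid, method, value))
    return out


def read_status_table(path: str | Path) -> dict[str, str]:
    """Read an annotation-status TSV: transcript_id, feature-type/status."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "transcript_id":
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected id, status")
            table[fields[0]] = fields[1]
    return table


def read_counts(
    path: str | Path,
) -> tuple[dict[tuple[str, str], int], dict[str, int]]:
    """Read a count table: transcript_id, library, read_count rows with
    ``#total_mapped=<library>:<count>`` header lines.

    Returns (counts keyed by (transcript_id, library), library totals).
    Totals come only from the headers — RPKM denominators are library-wide
    and are never re-derived from the transcript subset present.
    """
    counts: dict[tuple[str, str], int] = {}
    totals: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#total_mapped="):
                lib, _, n = line[len("#total_mapped=") :].partition(":")
                totals[lib] = int(n)
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "transcript_id":
                continue
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected id, library, count"
                )
            counts[(fields[0], fields[1])] = int(fields[2])
    return counts, totals


def write_counts(
    counts: Mapping[tuple[str, str], int],
    totals: Mapping[str, int],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        for lib in sorted(totals):
            fh.write(f"#total_mapped={lib}:{totals[lib]}\n")
        fh.write("transcript_id\tlibrary\tread_count\n")
        for (tid, lib), n in sorted(counts.items()):
            fh.write(f"{tid}\t{lib}\t{n}\n")


def load_thresholds(path: str | Path | None) -> ThresholdConfig:
    """Load a YAML config overriding any subset of the threshold defaults."""
    if path is None:
        return ThresholdConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(ThresholdConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return ThresholdConfig(**data)
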