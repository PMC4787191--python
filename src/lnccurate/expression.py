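"""Read trimming, RPKM quantification and expression/poly(A) flags.

The trimming rule drops 10 bp from the 5' end (random-primer artefacts),
trims 3'-terminal bases until a base with phred quality above 20 is
reached, and retains reads of at least 36 bp. RPKM is computed from raw
counts against the full mature-transcript length and a library-wide
mapped-read total:

    RPKM = count * 1e9 / (total_mapped * length_bp)

"Expressed" means RPKM strictly above 1. A transcript is called
poly(A)-minus under a stringent criterion: expressed in the ribo-zero
library but with literally zero signal (count 0, RPKM 0) in the
poly(A)-enriched library — any poly(A) signal disqualifies, because the
ribo-zero library also captures polyadenylated species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .core import ThresholdConfig


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: bases plus per-base phred qualities."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"{self.read_id}: bases/quals length mismatch")
        if any(q < 0 for q in self.quals):
            raise ValueError(f"{self.read_id}: negative quality")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ExpressionRecord:
    transcript_id: str
    library: str
    read_count: int
    rpkm: float

    def __post_init__(self) -> None:
        if self.read_count < 0 or self.rpkm < 0:
            raise ValueError("read_count and rpkm must be >= 0")


def trim_read(
    read: ReadRecord, thresholds: ThresholdConfig | None = None
) -> ReadRecord | None:
    """Apply the 5'/3' trimming rule; returns None for a discarded read.

    5': the first ``trim_head`` bases go unconditionally. 3': bases are
    removed from the end while their quality is <= ``trim_quality``,
    stopping at the first base (scanning 3'->5') above it. Reads shorter
    than ``trim_min_len`` afterwards are discarded.
    """
    t = thresholds or ThresholdConfig()
    start = t.trim_head
    end = len(read)
    while end > start and read.quals[end - 1] <= t.trim_quality:
        end -= 1
    if end - start < t.trim_min_len:
        return None
    return ReadRecord(read.read_id, read.bases[start:end], read.quals[start:end])


def trim_reads(
    reads: Sequence[ReadRecord], thresholds: ThresholdConfig | None = None
) -> tuple[list[ReadRecord], int]:
    """Trim a batch; returns (kept reads, number discarded)."""
    kept = []
    discarded = 0
    for r in reads:
        out = trim_read(r, thresholds)
        if out is None:
            discarded += 1
        else:
            kept.append(out)
    return kept, discarded


def read_fastq(path) -> list[ReadRecord]:
    """Load a phred+33 FASTQ into read records."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            ReadRecord(
                rec.id,
                str(rec.seq),
                tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return out


def write_fastq(reads: Sequence[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{quals}\n")


def compute_rpkm(
    read_count: int, transcript_length: int, total_mapped: int
) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if transcript_length <= 0:
        raise ValueError("transcript_length must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return read_count * 1e9 / (total_mapped * transcript_length)


def flag_expressed(rpkm: float, threshold: float = 1.0) -> bool:
    """Expressed means RPKM strictly greater than the threshold."""
    return rpkm > threshold


def infer_polya_minus(
    rpkm_ribozero: float, rpkm_polya: float, threshold: float = 1.0
) -> bool:
    """Poly(A)-minus call: expressed in ribo-zero, exactly zero in
    poly(A)-enriched. No epsilon on the zero — any signal disqualifies."""
    return rpkm_ribozero > threshold and rpkm_polya == 0.0


def quantify(
    counts: Mapping[tuple[str, str], int],
    totals: Mapping[str, int],
    lengths: Mapping[str, int],
) -> list[ExpressionRecord]:
    """Turn a (transcript, library) count map into expression records."""
    records = []
    for (tid, lib), n in sorted(counts.items()):
        if lib not in totals:
            raise ValueError(f"no total_mapped for library {lib!r}")
        if tid not in lengths:
            raise ValueError(f"no length for transcript {tid!r}")
        records.append(
            ExpressionRecord(
                tid, lib, n, compute_rpkm(n, lengths[tid], totals[lib])
            )
        )
    return records


def rpkm_matrix(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    """Transcripts x libraries RPKM matrix (missing cells 0)."""
    if not records:
        raise ValueError("no expression records")
    df = pd.DataFrame(
        [(r.transcript_id, r.library, r.rpkm) for r in records],
        columns=["transcript_id", "library", "rpkm"],
    )
    return (
        df.pivot_table(
            index="transcript_id", columns="library", values="rpkm", fill_value=0.0
        )
        .sort_index()
    )


def stage_profile(
    matrix: pd.DataFrame,
    biotypes: Mapping[str, str],
    expressed_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-stage mean RPKM and expressed counts split by biotype.

    ``matrix`` is transcripts x stages; every transcript needs a biotype
    (mRNA or lncRNA). Returns a frame indexed by (stage, biotype) with
    ``mean_rpkm`` and ``n_expressed`` columns.
    """
    if matrix.empty:
        raise ValueError("empty expression matrix")
    missing = [t for t in matrix.index if t not in biotypes]
    if missing:
        raise ValueError(f"transcripts without biotype: {missing[:5]}")
    bio = pd.Series({t: biotypes[t] for t in matrix.index}, name="biotype")
    rows = []
    for stage in matrix.columns:
        col = matrix[stage]
        for biotype, values in col.groupby(bio):
            rows.append(
                {
                    "stage": stage,
                    "biotype": biotype,
                    "mean_rpkm": float(values.mean()),
                    "n_expressed": int((values > expressed_threshold).sum()),
                }
            )
    return pd.DataFrame(rows).set_index(["stage", "biotype"])
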