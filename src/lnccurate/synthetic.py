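"""Seeded synthetic fixtures with planted ground truth for every stage.

The generator emulates the study conditions the pipeline targets: a toy
chromosome carrying non-overlapping multi-exon coding genes on both
strands (mature length centred on 2869 bp), lncRNA transcripts realizing
every positional class with planted labels (length centred on 1008 bp,
~94 % of exon-count mass on 1–3 exons), peak tracks with planted
presence/coverage per mark, paired poly(A)/ribo-zero count tables with a
planted poly(A)-minus subset, negative-binomial developmental-stage
counts with an 8-fold mRNA:lncRNA expression ratio, FASTQ reads engineered
around the trimming boundaries, and alignment fixtures exercising every
dedup branch.

Determinism: every fixture draws from its own substream derived from
``(seed, fixture-name)``, so one seed fixes every emitted byte and adding
a fixture never perturbs the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import (
    GeneModel,
    GenomicInterval,
    MINUS,
    PLUS,
    ThresholdConfig,
    TranscriptModel,
    UNKNOWN,
)
from .io import (
    AlignmentRecord,
    CodingPotentialRecord,
    PeakRecord,
    write_counts,
    write_peaks,
    write_transcripts,
)
from .expression import ReadRecord, write_fastq

CHROM = "chr2L"

DEFAULT_LNC_PER_CLASS: dict[str, int] = {
    # proportions echo the curated list: intergenic dominates, antisense
    # outnumbers sense in both overlap classes, a small unknown remainder
    "intergenic": 20,
    "exonic_antisense": 7,
    "exonic_sense": 3,
    "intronic_antisense": 5,
    "intronic_sense": 3,
    "unknown": 3,
}

SIGNATURE_PATTERNS = (
    (True, True, True),
    (False, False, False),
    (True, True, False),
    (True, False, True),
    (False, True, True),
    (True, False, False),
    (False, True, False),
    (False, False, True),
)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_coding_genes: int = 30
    n_lnc_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LNC_PER_CLASS)
    )
    chrom_length: int = 2_000_000
    lnc_length_mean: float = 1008.0
    mrna_length_mean: float = 2869.0
    lnc_exon_mass_1to3: float = 0.94
    mrna_to_lnc_expression_ratio: float = 8.0
    polya_minus_fraction: float = 0.13
    nb_dispersion: float = 0.3
    n_reads_fastq: int = 60
    n_stages: int = 30

    def __post_init__(self) -> None:
        if not 0 <= self.lnc_exon_mass_1to3 <= 1:
            raise ValueError("lnc_exon_mass_1to3 must be in [0, 1]")
        if not 0 <= self.polya_minus_fraction <= 1:
            raise ValueError("polya_minus_fraction must be in [0, 1]")
        if self.n_coding_genes < 0 or self.chrom_length <= 0:
            raise ValueError("counts and lengths must be positive")


@dataclass
class GroundTruth:
    """Planted truth, keyed by transcript or gene id."""

    lnc_class: dict[str, str] = field(default_factory=dict)
    strand: dict[str, str] = field(default_factory=dict)
    polya_minus: set[str] = field(default_factory=set)
    signatures: dict[str, tuple[bool, bool, bool]] = field(default_factory=dict)
    validation_group: dict[str, str] = field(default_factory=dict)
    cage_complete: dict[str, bool] = field(default_factory=dict)
    read_fates: dict[str, int | None] = field(default_factory=dict)
    dedup_kept: dict[str, set[str]] = field(default_factory=dict)
    funnel_survivors: set[str] = field(default_factory=set)

    def to_json(self) -> dict:
        return {
            "lnc_class": self.lnc_class,
            "strand": self.strand,
            "polya_minus": sorted(self.polya_minus),
            "signatures": {k: list(v) for k, v in self.signatures.items()},
            "validation_group": self.validation_group,
            "cage_complete": self.cage_complete,
            "read_fates": self.read_fates,
            "dedup_kept": {k: sorted(v) for k, v in self.dedup_kept.items()},
            "funnel_survivors": sorted(self.funnel_survivors),
        }


def _rng(config: SimulationConfig, fixture: str) -> np.random.Generator:
    sub = zlib.crc32(fixture.encode()) & 0x7FFFFFFF
    return np.random.default_rng([config.seed & 0x7FFFFFFF, sub])


def _exon_count(rng: np.random.Generator, mass_1to3: float) -> int:
    # within 1-3, single exons dominate (over half of all lncRNAs)
    if rng.random() < mass_1to3:
        return int(rng.choice([1, 2, 3], p=[0.60, 0.25, 0.15]))
    return int(rng.choice([4, 5], p=[0.7, 0.3]))


def _build_transcript(
    tid: str,
    gene_id: str,
    source: str,
    chrom: str,
    start: int,
    strand: str,
    mature_len: int,
    n_exons: int,
    intron_len: int = 120,
) -> TranscriptModel:
    """Lay out ``n_exons`` exons totalling ``mature_len`` from ``start``."""
    base = mature_len // n_exons
    lens = [base] * n_exons
    lens[-1] += mature_len - base * n_exons
    exons = []
    pos = start
    for ln in lens:
        exons.append(GenomicInterval(chrom, pos, pos + ln, strand))
        pos += ln + intron_len
    return TranscriptModel(tid, gene_id, source, tuple(exons))


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneModel], GroundTruth]:
    """Non-overlapping multi-exon coding genes on both strands.

    Introns are kept wide (>= 2600 bp) so intronic lncRNAs fit with
    margins; intergenic gaps (>= 4000 bp) leave room for intergenic
    lncRNAs, promoter windows and decoy peaks.
    """
    rng = _rng(config, "annotation")
    genes: list[GeneModel] = []
    cursor = 5000
    for i in range(config.n_coding_genes):
        strand = PLUS if i % 2 == 0 else MINUS
        exon_target = max(200, config.mrna_length_mean / 3)
        exon_lens = [
            int(max(150, rng.normal(exon_target, 80))) for _ in range(3)
        ]
        intron_lens = [int(rng.integers(2600, 4000)) for _ in range(2)]
        exons = []
        pos = cursor
        for k in range(3):
            exons.append(GenomicInterval(CHROM, pos, pos + exon_lens[k], strand))
            pos += exon_lens[k]
            if k < 2:
                pos += intron_lens[k]
        if pos > config.chrom_length:
            raise ValueError(
                f"chromosome of {config.chrom_length} bp cannot pack "
                f"{config.n_coding_genes} coding genes"
            )
        gid = f"cg{i + 1:04d}"
        tx = TranscriptModel(f"{gid}.t1", gid, "ucsc", tuple(exons))
        genes.append(GeneModel(gid, "coding", (tx,)))
        cursor = pos + int(rng.integers(4000, 8000))
    return genes, GroundTruth()


# ---------------------------------------------------------------------------
# lncRNAs


class _GapAllocator:
    """Hands out disjoint windows inside the intergenic gaps."""

    def __init__(
        self, genes: Sequence[GeneModel], chrom_length: int, margin: int = 800
    ) -> None:
        spans = sorted((g.span.start, g.span.end) for g in genes)
        self.gaps: list[list[int]] = []
        prev = 1000
        for s, e in spans:
            if s - margin > prev + margin:
                self.gaps.append([prev + margin, s - margin])
            prev = e
        self.gaps.append([prev + margin, chrom_length - margin])

    def take(self, width: int, pad: int = 700) -> int:
        for gap in self.gaps:
            if gap[1] - gap[0] >= width + pad:
                start = gap[0]
                gap[0] += width + pad
                return start
        raise ValueError(f"no intergenic gap of {width} bp left")


def generate_lncrnas(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: GroundTruth | None = None,
) -> tuple[list[TranscriptModel], GroundTruth]:
    """Place lncRNA transcripts realizing each requested class geometry."""
    rng = _rng(config, "lncrnas")
    truth = truth or GroundTruth()
    alloc = _GapAllocator(genes, config.chrom_length)
    lncs: list[TranscriptModel] = []
    # one gene-overlapping lncRNA per coding gene, so planted marks and
    # classes never interfere across plants
    host_iter = iter(range(len(genes)))
    counter = 0

    def draw_len(lo: int = 300, hi: int = 2400) -> int:
        return int(np.clip(rng.normal(config.lnc_length_mean, 250), lo, hi))

    for lnc_class in sorted(config.n_lnc_per_class):
        n = config.n_lnc_per_class[lnc_class]
        for _ in range(n):
            counter += 1
            tid = f"lnc{counter:04d}"
            if lnc_class in ("intergenic", "unknown"):
                k = _exon_count(rng, config.lnc_exon_mass_1to3)
                length = draw_len()
                width = length + (k - 1) * 120
                # wide padding keeps planted promoter and CAGE windows of
                # neighbouring lncRNA genes from touching
                start = alloc.take(width, pad=1800)
                strand = (
                    UNKNOWN
                    if lnc_class == "unknown"
                    else (PLUS if counter % 2 else MINUS)
                )
                tx = _build_transcript(
                    tid, tid, "flybase", CHROM, start, strand, length, k
                )
            else:
                try:
                    host = genes[next(host_iter)]
                except StopIteration:
                    raise ValueError(
                        "not enough coding genes to host gene-overlapping "
                        "lncRNA plants"
                    ) from None
                sense = lnc_class.endswith("_sense")
                strand = (
                    host.strand
                    if sense
                    else (MINUS if host.strand == PLUS else PLUS)
                )
                host_tx = host.transcripts[0]
                mid_exon = host_tx.exons[1]
                intron_after = (
                    host_tx.exons[1].end,
                    host_tx.exons[2].start,
                )
                if lnc_class.startswith("exonic"):
                    # one exon straddling the host's middle exon 3' edge
                    length = min(draw_len(), len(mid_exon) // 2 + 600)
                    over = min(len(mid_exon) // 2, length // 2)
                    start = mid_exon.end - over
                    exons = [
                        GenomicInterval(CHROM, start, start + length, strand)
                    ]
                    tx = TranscriptModel(
                        tid, tid, "flybase", tuple(exons)
                    )
                else:  # intronic: contained in the intron, no exon contact
                    lo, hi = intron_after
                    avail = hi - lo - 200
                    k = int(rng.choice([1, 2], p=[0.7, 0.3]))
                    length = int(
                        np.clip(rng.normal(800, 150), 300, avail - (k - 1) * 120)
                    )
                    tx = _build_transcript(
                        tid, tid, "flybase", CHROM, lo + 100, strand, length, k
                    )
                    assert tx.span.end <= hi - 100
            lncs.append(tx)
            truth.lnc_class[tid] = lnc_class
            truth.strand[tid] = tx.strand
    return lncs, truth


def lnc_genes(lncs: Sequence[TranscriptModel]) -> list[GeneModel]:
    return [GeneModel(t.gene_id, "lncRNA", (t,)) for t in lncs]


# ---------------------------------------------------------------------------
# peaks


def generate_peaks(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    lncs: Sequence[TranscriptModel],
    truth: GroundTruth,
    thresholds: ThresholdConfig | None = None,
) -> tuple[list[PeakRecord], GroundTruth]:
    """Plant chromatin marks on lncRNA genes and CAGE peaks at 5' ends.

    Known-strand lnc genes cycle through all eight presence patterns of
    (H3K4me3, H3K36me3, Pol II); flagged marks get peaks realizing them
    (~70 % body coverage for K36, ~60 % for Pol II), unflagged genes stay
    clear of peaks, and decoy peaks of every mark land in unoccupied gaps.
    """
    from .chromatin import promoter_window

    t = thresholds or ThresholdConfig()
    rng = _rng(config, "peaks")
    peaks: list[PeakRecord] = []
    alloc = _GapAllocator(
        list(genes) + lnc_genes(lncs), config.chrom_length, margin=1200
    )

    for i, lg in enumerate(lnc_genes(lncs)):
        if lg.strand == UNKNOWN:
            truth.signatures[lg.gene_id] = (False, False, False)
            continue
        k4, k36, pol = SIGNATURE_PATTERNS[i % len(SIGNATURE_PATTERNS)]
        truth.signatures[lg.gene_id] = (k4, k36, pol)
        span = lg.span
        if k4:
            win = promoter_window(lg.tss, lg.strand, lg.chrom, t)
            mid = (win.start + win.end) // 2
            peaks.append(
                PeakRecord(
                    GenomicInterval(CHROM, mid - 75, mid + 75),
                    "H3K4me3",
                    "sim_k4",
                )
            )
        if k36:
            covered = int(len(span) * 0.7)
            peaks.append(
                PeakRecord(
                    GenomicInterval(CHROM, span.start, span.start + covered),
                    "H3K36me3",
                    "sim_k36",
                )
            )
        if pol:
            covered = max(50, int(len(span) * 0.6))
            peaks.append(
                PeakRecord(
                    GenomicInterval(CHROM, span.end - covered, span.end),
                    "PolII",
                    "sim_pol",
                )
            )

    # CAGE completeness plants, alternating ~55 % true
    for j, tx in enumerate(lncs):
        if tx.strand == UNKNOWN:
            continue
        flag = (j % 9) not in (2, 5, 7, 8)
        truth.cage_complete[tx.transcript_id] = flag
        if flag:
            five = tx.five_prime
            peaks.append(
                PeakRecord(
                    GenomicInterval(CHROM, max(0, five - 10), five + 11),
                    "CAGE",
                    "sim_cage",
                )
            )

    for mark in ("H3K4me3", "H3K36me3", "PolII", "CAGE"):
        for _ in range(4):
            width = int(rng.integers(150, 400))
            start = alloc.take(width, pad=900)
            peaks.append(
                PeakRecord(
                    GenomicInterval(CHROM, start, start + width),
                    mark,
                    "sim_decoy",
                )
            )
    return peaks, truth


# ---------------------------------------------------------------------------
# expression


LIB_POLYA = "polyA"
LIB_RIBOZERO = "ribozero"

LIBRARY_TOTALS = {LIB_POLYA: 5_000_000, LIB_RIBOZERO: 8_000_000}
STAGE_TOTAL = 4_000_000

# target mean RPKM levels behind the negative-binomial stage counts
LNC_MEAN_RPKM = 5.0


def _nb(rng: np.random.Generator, mu: float, phi: float) -> int:
    if mu <= 0:
        return 0
    n = 1.0 / phi
    p = n / (n + mu)
    return int(rng.negative_binomial(n, p))


def generate_expression(
    config: SimulationConfig,
    coding: Sequence[GeneModel],
    lncs: Sequence[TranscriptModel],
    truth: GroundTruth,
    thresholds: ThresholdConfig | None = None,
) -> tuple[dict[tuple[str, str], int], dict[str, int], GroundTruth]:
    """Counts for the two brain libraries and the developmental stages.

    Stage counts are negative-binomial with mean proportional to
    transcript length times a biotype level, mRNA level 8x the lncRNA
    level, so the expected RPKM ratio equals the configured fold change.
    Planted poly(A)-minus transcripts get zero poly(A) counts and
    ribo-zero counts comfortably above the expressed threshold; planted
    validation-group genes get poly(A) counts pinning their RPKM into the
    configured quartile bands.
    """
    t = thresholds or ThresholdConfig()
    rng = _rng(config, "expression")
    counts: dict[tuple[str, str], int] = {}
    totals = dict(LIBRARY_TOTALS)
    stages = [f"stage{i + 1:02d}" for i in range(config.n_stages)]
    for s in stages:
        totals[s] = STAGE_TOTAL

    all_tx = [g.transcripts[0] for g in coding] + list(lncs)
    biotype = {g.transcripts[0].transcript_id: "mRNA" for g in coding}
    biotype.update({tx.transcript_id: "lncRNA" for tx in lncs})

    # validation groups: cross all-three / none-of-three signature plants
    # with high/low expression, alternating
    def rpkm_to_count(rpkm: float, length: int, total: int) -> int:
        return max(1, round(rpkm * total * length / 1e9))

    hi_lo = {"all": 0, "none": 0}
    pinned: dict[str, int] = {}
    for tx in lncs:
        sig = truth.signatures.get(tx.gene_id)
        if sig is None:
            continue
        if sig == (True, True, True):
            key = "all"
        elif sig == (False, False, False) and tx.strand != UNKNOWN:
            key = "none"
        else:
            continue
        high = hi_lo[key] % 2 == 0
        hi_lo[key] += 1
        target = t.rpkm_q3 * 1.8 if high else (t.rpkm_q1 + t.rpkm_expressed) / 2
        pinned[tx.transcript_id] = rpkm_to_count(
            target, tx.length, totals[LIB_POLYA]
        )
        group = {
            ("all", True): "G1",
            ("all", False): "G2",
            ("none", True): "G3",
            ("none", False): "G4",
        }[(key, high)]
        truth.validation_group[tx.gene_id] = group

    # poly(A)-minus plants among the remaining lncRNAs
    candidates = [
        tx.transcript_id
        for tx in lncs
        if tx.transcript_id not in pinned
    ]
    n_minus = round(config.polya_minus_fraction * len(lncs))
    truth.polya_minus = set(candidates[:n_minus])

    lnc_level = LNC_MEAN_RPKM
    mrna_level = lnc_level * config.mrna_to_lnc_expression_ratio
    for tx in all_tx:
        tid = tx.transcript_id
        level = mrna_level if biotype[tid] == "mRNA" else lnc_level
        for lib in (LIB_POLYA, LIB_RIBOZERO):
            total = totals[lib]
            if tid in truth.polya_minus:
                if lib == LIB_POLYA:
                    counts[(tid, lib)] = 0
                else:
                    counts[(tid, lib)] = rpkm_to_count(
                        4 * t.rpkm_expressed, tx.length, total
                    )
                continue
            if tid in pinned and lib == LIB_POLYA:
                counts[(tid, lib)] = pinned[tid]
                continue
            mu = level * total * tx.length / 1e9
            n = _nb(rng, mu, config.nb_dispersion)
            # a transcript not planted poly(A)-minus must keep >=1 poly(A)
            # read, so the stringent zero criterion recovers the plant set
            if lib == LIB_POLYA and n == 0:
                n = 1
            counts[(tid, lib)] = n
        for s in stages:
            mu = level * totals[s] * tx.length / 1e9
            counts[(tid, s)] = _nb(rng, mu, config.nb_dispersion)
    return counts, totals, truth


# ---------------------------------------------------------------------------
# reads


def generate_reads(
    config: SimulationConfig, thresholds: ThresholdConfig | None = None
) -> tuple[list[ReadRecord], GroundTruth]:
    """FASTQ fixtures bracketing the trimming boundaries.

    Engineered reads carry their expected post-trim length (or None for a
    discard) in the ground truth; additional random reads exercise the
    rule on realistic decaying 3' quality tails.
    """
    t = thresholds or ThresholdConfig()
    rng = _rng(config, "reads")
    truth = GroundTruth()
    reads: list[ReadRecord] = []

    def add(rid: str, quals: list[int], fate: int | None) -> None:
        bases = "".join(rng.choice(list("ACGT"), size=len(quals)))
        reads.append(ReadRecord(rid, bases, tuple(quals)))
        truth.read_fates[rid] = fate

    q = t.trim_quality
    # kept exactly at the minimum length: no 3' trim applies
    add("eng_keep_min", [q + 10] * (t.trim_head + t.trim_min_len), t.trim_min_len)
    # one base short of the minimum: discarded
    add("eng_short", [q + 10] * (t.trim_head + t.trim_min_len - 1), None)
    # low-quality tail with a rescuing high base one position in
    add("eng_tail_stop", [q + 10] * 45 + [q - 5, q + 5, q - 2], 37)
    # boundary quality (== threshold) is trimmed
    add("eng_tail_eq", [q + 10] * 46 + [q], 36)
    # entire read below threshold after the 5' cut
    add("eng_all_tail", [q + 10] * t.trim_head + [q - 1] * 40, None)

    for i in range(config.n_reads_fastq):
        head = [int(x) for x in rng.integers(q + 5, q + 20, size=80)]
        tail = [int(x) for x in np.clip(rng.integers(2, q + 8, size=10), 0, 60)]
        bases = "".join(rng.choice(list("ACGT"), size=90))
        reads.append(ReadRecord(f"rand{i:03d}", bases, tuple(head + tail)))
    return reads, truth


# ---------------------------------------------------------------------------
# dedup / rRNA alignment fixtures


@dataclass
class AlignmentFixtures:
    primary: list[TranscriptModel]
    brown_candidates: list[TranscriptModel]
    young_candidates: list[TranscriptModel]
    rrna_queries: list[TranscriptModel]
    alignments: list[AlignmentRecord]
    rrna_alignments: list[AlignmentRecord]
    flybase_id_map: dict[str, str]
    lengths: dict[str, int]

    @property
    def brown_alignments(self) -> list[AlignmentRecord]:
        ids = {t.transcript_id for t in self.brown_candidates}
        return [a for a in self.alignments if a.query_id in ids]

    @property
    def young_alignments(self) -> list[AlignmentRecord]:
        ids = {t.transcript_id for t in self.young_candidates}
        return [a for a in self.alignments if a.query_id in ids]


def generate_alignment_fixtures(
    config: SimulationConfig,
) -> tuple[AlignmentFixtures, GroundTruth]:
    """Transcripts plus alignment records realizing every dedup branch.

    Plants: a same-loci pair, a 0.6-overlap single-exon candidate, a
    0.6-overlap candidate whose exon count differs (multi-exon
    exemption), a FlyBase-ID duplicate, sub-threshold overlap keeps, 0.70
    and 0.95 coverage candidates for the 90 % rule, and ribosomal hits at
    the three threshold corners.
    """
    truth = GroundTruth()
    base = 10_000

    def tx(tid: str, start: int, n_exons: int, mature: int, strand=PLUS, src="flybase"):
        return _build_transcript(
            tid, tid, src, CHROM, start, strand, mature, n_exons, intron_len=200
        )

    p1 = tx("FBtr_P1", base, 2, 1000)
    p2 = tx("FBtr_P2", base + 20_000, 1, 800)
    p3 = tx("FBtr_P3", base + 40_000, 3, 1200)
    primary = [p1, p2, p3]

    # brown-rule candidates
    c_same = TranscriptModel("BR_same", "BR_same", "brown", p1.exons)
    c_single = tx("BR_single", base + 200, 1, 1000, src="brown")
    c_multi = tx("BR_multi", base + 200, 3, 1000, src="brown")
    c_low = tx("BR_low", base + 60_000, 1, 1000, src="brown")
    c_dup = tx("BR_dup", base + 80_000, 1, 900, src="brown")
    brown = [c_same, c_single, c_multi, c_low, c_dup]
    truth.dedup_kept["brown"] = {"BR_multi", "BR_low"}

    # young-vs-brown candidates (queries are the brown-side transcripts)
    y_70 = tx("YB_70", base + 100_000, 1, 1000, src="brown")
    y_95 = tx("YB_95", base + 120_000, 1, 1000, src="brown")
    y_same = TranscriptModel("YB_same", "YB_same", "brown", p2.exons)
    young = [y_70, y_95, y_same]
    truth.dedup_kept["young_vs_brown"] = {"YB_70"}

    lengths = {
        t.transcript_id: t.length
        for t in primary + brown + young
    }
    lengths.update({"rRNA_1": 1800, "rRNA_2": 1800})

    def aln(q, s, frac_q, e=1e-20, ident=97.0, same_loci=False):
        alen = int(frac_q * lengths[q])
        return AlignmentRecord(
            query_id=q,
            subject_id=s,
            e_value=e,
            identity_pct=ident,
            overlap_fraction_query=min(1.0, alen / lengths[q]),
            overlap_fraction_subject=min(1.0, alen / lengths[s]),
            same_loci=same_loci,
        )

    alignments = [
        aln("BR_same", "FBtr_P1", 1.0, same_loci=True),
        aln("BR_single", "FBtr_P1", 0.6),
        aln("BR_multi", "FBtr_P1", 0.6),
        aln("BR_low", "FBtr_P1", 0.3),
        # the 90 % rule denominator is the candidate's own length
        aln("YB_70", "FBtr_P2", 0.70),
        aln("YB_95", "FBtr_P2", 0.95),
        aln("YB_same", "FBtr_P2", 1.0, same_loci=True),
    ]

    rrna_queries = [
        tx("RR_hit", base + 140_000, 1, 1100),
        tx("RR_ident_low", base + 160_000, 1, 1100),
        tx("RR_evalue_high", base + 180_000, 1, 1100),
    ]
    lengths.update({t.transcript_id: t.length for t in rrna_queries})
    rrna_alignments = [
        AlignmentRecord("RR_hit", "rRNA_1", 1e-12, 99.5, 0.9, 0.5),
        AlignmentRecord("RR_ident_low", "rRNA_1", 1e-12, 98.0, 0.9, 0.5),
        AlignmentRecord("RR_evalue_high", "rRNA_2", 1e-8, 100.0, 0.9, 0.5),
    ]
    truth.dedup_kept["rrna"] = {"RR_ident_low", "RR_evalue_high"}

    fixtures = AlignmentFixtures(
        primary=primary,
        brown_candidates=brown,
        young_candidates=young,
        rrna_queries=rrna_queries,
        alignments=alignments,
        rrna_alignments=rrna_alignments,
        flybase_id_map={"BR_dup": "FBtr_P2"},
        lengths=lengths,
    )
    return fixtures, truth


def write_alignment_tabular(
    alignments: Sequence[AlignmentRecord],
    lengths: Mapping[str, int],
    path,
) -> None:
    """Serialize alignment records as 12-column BLAST-style tabular."""
    with open(path, "w") as fh:
        for a in alignments:
            alen = round(a.overlap_fraction_query * lengths[a.query_id])
            fh.write(
                "\t".join(
                    [
                        a.query_id,
                        a.subject_id,
                        f"{a.identity_pct:.2f}",
                        str(alen),
                        "0",
                        "0",
                        "1",
                        str(alen),
                        "1",
                        str(alen),
                        f"{a.e_value:.3g}",
                        "100.0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# discovery funnel fixture


@dataclass
class DiscoveryFixture:
    assembled: list[list[TranscriptModel]]  # one list per library
    reference: list[TranscriptModel]
    scores: list[CodingPotentialRecord]
    rrna_alignments: list[AlignmentRecord]
    remap_counts: dict[str, int]
    updated_annotation: list[TranscriptModel]


def generate_discovery_fixture(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
) -> tuple[DiscoveryFixture, GroundTruth]:
    """Assembled-transcript set with one planted fate per funnel stage.

    20 genuine lncRNAs survive; decoys are removed at each stage: overlap
    with the old annotation, sub-200-bp length, coding potential at or
    above the cutoff, ribosomal identity, zero remapped reads, and sense
    overlap with newly annotated coding genes.
    """
    rng = _rng(config, "discovery")
    truth = GroundTruth()
    reference = [g.transcripts[0] for g in genes]
    alloc = _GapAllocator(genes, config.chrom_length)
    assembled: list[TranscriptModel] = []
    scores: list[CodingPotentialRecord] = []
    remap_counts: dict[str, int] = {}
    rrna_alignments: list[AlignmentRecord] = []
    updated: list[TranscriptModel] = []

    def place(tid: str, length: int, strand=PLUS) -> TranscriptModel:
        start = alloc.take(length + 300)
        t = _build_transcript(tid, tid, "novel", CHROM, start, strand, length, 1)
        assembled.append(t)
        return t

    def score(tid: str, value: float) -> None:
        scores.append(CodingPotentialRecord(tid, "cpat_probability", value))

    for i in range(20):
        tid = f"NOV_true{i:02d}"
        place(tid, int(rng.integers(400, 1500)), PLUS if i % 2 else MINUS)
        score(tid, float(rng.uniform(0.01, 0.30)))
        remap_counts[tid] = int(rng.integers(3, 40))
        truth.funnel_survivors.add(tid)
    for i in range(5):
        tid = f"NOV_short{i}"
        place(tid, int(rng.integers(80, 199)))
        score(tid, 0.05)
        remap_counts[tid] = 5
    for i in range(5):
        tid = f"NOV_coding{i}"
        place(tid, 900)
        # one exactly at the cutoff: a probability at 0.39 is coding
        score(tid, 0.39 if i == 0 else float(rng.uniform(0.5, 0.95)))
        remap_counts[tid] = 5
    for i in range(2):
        tid = f"NOV_rrna{i}"
        place(tid, 1100)
        score(tid, 0.05)
        remap_counts[tid] = 5
        rrna_alignments.append(
            AlignmentRecord(tid, "rRNA_1", 1e-15, 99.6, 0.9, 0.6)
        )
    for i in range(3):
        tid = f"NOV_nosupport{i}"
        place(tid, 800)
        score(tid, 0.05)
        remap_counts[tid] = 0
    for i in range(3):
        tid = f"NOV_sense{i}"
        t = place(tid, 700, PLUS)
        score(tid, 0.05)
        remap_counts[tid] = 5
        # a newly annotated coding gene overlapping it on the same strand
        sp = t.span
        updated.append(
            _build_transcript(
                f"NEWCG{i}", f"NEWCG{i}", "ucsc", CHROM, sp.start - 100,
                PLUS, len(sp) + 200, 1,
            )
        )
    for i in range(4):
        tid = f"NOV_annotated{i}"
        host = genes[i].transcripts[0]
        exon = host.exons[0]
        t = TranscriptModel(
            tid,
            tid,
            "novel",
            (GenomicInterval(CHROM, exon.start + 10, exon.start + 610, PLUS),),
        )
        assembled.append(t)
        score(tid, 0.05)
        remap_counts[tid] = 5

    # both libraries assemble the same structures; the union collapses them
    lib1 = list(assembled)
    lib2 = [
        TranscriptModel(t.transcript_id, t.gene_id, t.source, t.exons)
        for t in assembled
    ]
    fixture = DiscoveryFixture(
        assembled=[lib1, lib2],
        reference=reference,
        scores=scores,
        rrna_alignments=rrna_alignments,
        remap_counts=remap_counts,
        updated_annotation=updated,
    )
    return fixture, truth


# ---------------------------------------------------------------------------
# master entry point


def generate_all(config: SimulationConfig, outdir) -> GroundTruth:
    """Write every fixture to ``outdir`` and return the merged truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, truth = generate_annotation(config)
    lncs, truth = generate_lncrnas(config, genes, truth)
    peaks, truth = generate_peaks(config, genes, lncs, truth)
    counts, totals, truth = generate_expression(config, genes, lncs, truth)
    reads, read_truth = generate_reads(config)
    truth.read_fates = read_truth.read_fates
    fixtures, aln_truth = generate_alignment_fixtures(config)
    truth.dedup_kept = aln_truth.dedup_kept
    disc, disc_truth = generate_discovery_fixture(config, genes)
    truth.funnel_survivors = disc_truth.funnel_survivors

    write_transcripts([g.transcripts[0] for g in genes], outdir / "coding.gtf")
    write_transcripts(lncs, outdir / "lncrnas.gtf")
    for mark in ("H3K4me3", "H3K36me3", "PolII", "CAGE"):
        write_peaks(
            [p for p in peaks if p.mark == mark],
            outdir / f"peaks_{mark}.bed",
        )
    write_counts(counts, totals, outdir / "counts.tsv")
    write_fastq(reads, outdir / "reads.fastq")
    write_alignment_tabular(
        fixtures.alignments, fixtures.lengths, outdir / "alignments.tsv"
    )
    with open(outdir / "lengths.tsv", "w") as fh:
        for tid in sorted(fixtures.lengths):
            fh.write(f"{tid}\t{fixtures.lengths[tid]}\n")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth.to_json(), fh, indent=2, sort_keys=True)
    return truth
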