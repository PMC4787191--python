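"""Funnel accounting, summary tables and RT-qPCR detection calls.

RT-qPCR abundance is expressed as −ΔCt = Ct(reference) − mean Ct(target
replicates); a target is detected when −ΔCt reaches the cutoff (1 cycle
for the brain panel, 2 for the whole-body panel). The reference gene's Ct
is an explicit input. Detection rates and other percentages are rounded
half-up to two decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from statistics import mean, stdev
from typing import Mapping, Sequence

from .classification import ClassificationResult
from .core import MINUS, PLUS, TranscriptModel, UNKNOWN
from .discovery import FunnelReport, FunnelStage


@dataclass(frozen=True)
class QpcrRecord:
    target_id: str
    ct_replicates: tuple[float, ...]
    reference_ct: float
    minus_delta_ct: float
    detected: bool


def round_half_up(value: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def qpcr_call(
    target_id: str,
    ct_replicates: Sequence[float],
    reference_ct: float,
    cutoff: float,
) -> QpcrRecord:
    """Compute −ΔCt and the detection call for one target."""
    if not ct_replicates:
        raise ValueError(f"{target_id}: no Ct replicates")
    mdc = reference_ct - mean(ct_replicates)
    return QpcrRecord(
        target_id=target_id,
        ct_replicates=tuple(ct_replicates),
        reference_ct=reference_ct,
        minus_delta_ct=mdc,
        detected=mdc >= cutoff,
    )


def detection_rate(calls: Sequence[QpcrRecord]) -> float:
    """Percent of targets detected, rounded half-up to 2 decimals."""
    if not calls:
        raise ValueError("no qPCR calls")
    return round_half_up(100.0 * sum(c.detected for c in calls) / len(calls))


def funnel_check(stages: Sequence[FunnelStage]) -> FunnelReport:
    """Validate a funnel's internal arithmetic and stage chaining."""
    for s in stages:  # FunnelStage re-validates its own arithmetic
        if s.count_out != s.count_in - s.removed:
            raise ValueError(f"stage {s.name}: arithmetic broken")
    for a, b in zip(stages, stages[1:]):
        if a.count_out != b.count_in:
            raise ValueError(
                f"stage chain broken between {a.name} (out {a.count_out}) "
                f"and {b.name} (in {b.count_in})"
            )
    return FunnelReport(list(stages))


def direction_table(
    transcripts: Sequence[TranscriptModel],
) -> dict[str, dict[str, int]]:
    """Counts by source x transcriptional direction, with totals.

    Mirrors the per-source direction bookkeeping of the curated list:
    rows +, -, unknown and a total per source.
    """
    table: dict[str, dict[str, int]] = {}
    for t in transcripts:
        row = table.setdefault(
            t.source, {PLUS: 0, MINUS: 0, UNKNOWN: 0, "total": 0}
        )
        row[t.strand] += 1
        row["total"] += 1
    return table


def class_table(
    transcripts: Sequence[TranscriptModel],
    classifications: Sequence[ClassificationResult],
) -> dict[str, dict]:
    """Per-class summary: count, mean length ± sample sd, single/multi
    exon split, strand split — plus a grand total row."""
    by_id = {t.transcript_id: t for t in transcripts}
    classes: dict[str, list[TranscriptModel]] = {}
    for c in classifications:
        classes.setdefault(c.lnc_class, []).append(by_id[c.transcript_id])
    out: dict[str, dict] = {}
    for name, txs in sorted(classes.items()):
        lengths = [t.length for t in txs]
        out[name] = {
            "count": len(txs),
            "mean_length": round_half_up(mean(lengths)),
            "sd_length": round_half_up(stdev(lengths)) if len(txs) > 1 else 0.0,
            "single_exon": sum(t.exon_count == 1 for t in txs),
            "multi_exon": sum(t.exon_count > 1 for t in txs),
            "plus": sum(t.strand == PLUS for t in txs),
            "minus": sum(t.strand == MINUS for t in txs),
        }
    out["total"] = {"count": sum(v["count"] for v in out.values())}
    return out


def report_json(
    funnel: FunnelReport | None = None,
    direction: Mapping[str, Mapping[str, int]] | None = None,
    classes: Mapping[str, Mapping] | None = None,
    qpcr: Sequence[QpcrRecord] | None = None,
    path=None,
) -> dict:
    """Bundle every computed count into one machine-readable report."""
    payload: dict = {}
    if funnel is not None:
        payload["funnel"] = [
            {"stage": n, "in": i, "removed": r, "out": o}
            for n, i, r, o in funnel.to_rows()
        ]
    if direction is not None:
        payload["direction"] = {k: dict(v) for k, v in direction.items()}
    if classes is not None:
        payload["classes"] = {k: dict(v) for k, v in classes.items()}
    if qpcr is not None:
        payload["qpcr"] = {
            "n": len(qpcr),
            "n_detected": sum(c.detected for c in qpcr),
            "detection_rate_pct": detection_rate(qpcr),
        }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    return payload
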