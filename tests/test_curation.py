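import pytest

from lnccurate.core import GenomicInterval, ThresholdConfig, TranscriptModel
from lnccurate.curation import (
    apply_status_filter,
    dedup_against_primary,
    exclude_rrna,
    filter_min_length,
    overlap_groups,
)
from lnccurate.io import AlignmentRecord


def tx(tid, length=1000, n_exons=1, start=0, strand="+", source="flybase"):
    per = length // n_exons
    exons = []
    pos = start
    for i in range(n_exons):
        ln = per if i < n_exons - 1 else length - per * (n_exons - 1)
        exons.append(GenomicInterval("chr2L", pos, pos + ln, strand))
        pos += ln + 200
    return TranscriptModel(tid, tid, source, tuple(exons))


def aln(q, s, frac_q=0.0, frac_s=0.0, e=1e-20, ident=97.0, same_loci=False):
    return AlignmentRecord(q, s, e, ident, frac_q, frac_s, same_loci)


class TestMinLength:
    def test_boundary_is_kept(self):
        txs = [tx("a", 150), tx("b", 200), tx("c", 1008)]
        kept, decisions = filter_min_length(txs, 200)
        assert [t.transcript_id for t in kept] == ["b", "c"]
        assert {d.transcript_id: d.reason for d in decisions}["a"] == "too_short"

    def test_empty_and_identity(self):
        assert filter_min_length([], 200) == ([], [])
        txs = [tx("a", 300), tx("b", 200)]
        kept, _ = filter_min_length(txs, 200)
        assert kept == txs


class TestDedup:
    def test_same_loci_removed(self):
        p = tx("P", 1000)
        c = tx("C", 1000, source="ucsc")
        kept, decisions = dedup_against_primary(
            [c], [p], [aln("C", "P", 1.0, 1.0, same_loci=True)], "flybase_ucsc"
        )
        assert kept == []
        assert decisions[0].reason == "same_loci"

    def test_flybase_ucsc_uses_candidate_length(self):
        p = tx("P", 1000)
        kept, decisions = dedup_against_primary(
            [tx("C", 1000, source="ucsc")],
            [p],
            [aln("C", "P", 0.5, 0.2)],
            "flybase_ucsc",
        )
        assert kept == []  # >= 0.5 of the candidate's own length
        kept, _ = dedup_against_primary(
            [tx("C", 1000, source="ucsc")],
            [p],
            [aln("C", "P", 0.4, 0.9)],  # subject fraction plays no role here
            "flybase_ucsc",
        )
        assert len(kept) == 1

    def test_brown_single_exon_overlap_removed(self):
        p = tx("P", 1000, n_exons=2)
        c = tx("C", 1000, n_exons=1, source="brown")
        kept, decisions = dedup_against_primary(
            [c], [p], [aln("C", "P", 0.6, 0.6)], "brown"
        )
        assert kept == []
        assert decisions[0].reason == "overlap_50"

    def test_brown_multi_exon_exemption(self):
        """A multi-exon candidate with a differing exon count survives."""
        p = tx("P", 1000, n_exons=2)
        c = tx("C", 1000, n_exons=3, source="brown")
        kept, _ = dedup_against_primary(
            [c], [p], [aln("C", "P", 0.6, 0.6)], "brown"
        )
        assert [t.transcript_id for t in kept] == ["C"]

    def test_brown_same_exon_count_not_exempt(self):
        p = tx("P", 1000, n_exons=3)
        c = tx("C", 1000, n_exons=3, source="brown")
        kept, _ = dedup_against_primary(
            [c], [p], [aln("C", "P", 0.6, 0.6)], "brown"
        )
        assert kept == []

    def test_brown_uses_max_of_either_fraction(self):
        p = tx("P", 3000, n_exons=2)
        c = tx("C", 1000, n_exons=1, source="brown")
        kept, _ = dedup_against_primary(
            [c], [p], [aln("C", "P", 0.3, 0.8)], "brown"
        )
        assert kept == []

    def test_brown_flybase_id_duplicate(self):
        p = tx("FBtr1", 1000)
        c = tx("C", 1000, source="brown")
        kept, decisions = dedup_against_primary(
            [c], [p], [], "brown", flybase_id_map={"C": "FBtr1"}
        )
        assert kept == []
        assert decisions[0].reason == "flybase_id_duplicate"

    def test_young_rule_90_percent(self):
        p = tx("Y", 1000)
        keep_me = tx("C1", 1000, source="brown")
        drop_me = tx("C2", 1000, source="brown")
        kept, decisions = dedup_against_primary(
            [keep_me, drop_me],
            [p],
            [aln("C1", "Y", 0.7, 0.7), aln("C2", "Y", 0.95, 0.95)],
            "young_vs_brown",
        )
        assert [t.transcript_id for t in kept] == ["C1"]
        assert decisions[1].reason == "overlap_90"

    def test_evalue_ceiling_gates_evidence(self):
        p = tx("P", 1000)
        c = tx("C", 1000, source="ucsc")
        kept, _ = dedup_against_primary(
            [c], [p], [aln("C", "P", 0.9, 0.9, e=1e-5)], "flybase_ucsc"
        )
        assert len(kept) == 1  # alignment above the ceiling is ignored

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            dedup_against_primary([], [], [], "bogus")

    def test_alignment_with_absent_subject_rejected(self):
        with pytest.raises(ValueError, match="absent transcript"):
            dedup_against_primary(
                [tx("C")], [tx("P")], [aln("C", "ghost", 0.5)], "flybase_ucsc"
            )

    def test_alignment_with_foreign_query_is_ignored(self):
        kept, _ = dedup_against_primary(
            [tx("C")], [tx("P")], [aln("other", "P", 0.9)], "flybase_ucsc"
        )
        assert len(kept) == 1

    def test_coordinate_fallback_matches_alignment_route(self):
        """Without alignments, genomic exon overlap drives the same rules."""
        p = tx("P", 1000, start=0)
        dup = TranscriptModel("DUP", "DUP", "ucsc", p.exons)
        half = tx("HALF", 1000, start=500, source="ucsc")  # 50% overlap
        clear = tx("CLEAR", 1000, start=5000, source="ucsc")
        kept, decisions = dedup_against_primary(
            [dup, half, clear], [p], None, "flybase_ucsc"
        )
        assert [t.transcript_id for t in kept] == ["CLEAR"]
        assert all(d.provenance == "coordinate_fallback" for d in decisions)

    def test_dedup_idempotent(self, alignment_fixtures):
        fx, truth = alignment_fixtures
        kept, _ = dedup_against_primary(
            fx.brown_candidates,
            fx.primary,
            fx.brown_alignments,
            "brown",
            flybase_id_map=fx.flybase_id_map,
        )
        again, decisions = dedup_against_primary(
            kept,
            fx.primary,
            fx.brown_alignments,
            "brown",
            flybase_id_map=fx.flybase_id_map,
        )
        assert again == kept
        assert all(d.kept for d in decisions)

    def test_planted_partition_recovered(self, alignment_fixtures):
        fx, truth = alignment_fixtures
        kept_b, _ = dedup_against_primary(
            fx.brown_candidates,
            fx.primary,
            fx.brown_alignments,
            "brown",
            flybase_id_map=fx.flybase_id_map,
        )
        assert {t.transcript_id for t in kept_b} == truth.dedup_kept["brown"]
        kept_y, _ = dedup_against_primary(
            fx.young_candidates, fx.primary, fx.young_alignments, "young_vs_brown"
        )
        assert {
            t.transcript_id for t in kept_y
        } == truth.dedup_kept["young_vs_brown"]


class TestRrnaExclusion:
    @pytest.mark.parametrize(
        "e, ident, removed",
        [
            (1e-12, 99.5, True),
            (1e-12, 98.0, False),  # identity at/below the floor survives
            (1e-8, 100.0, False),  # E-value above the ceiling survives
        ],
    )
    def test_joint_thresholds(self, e, ident, removed):
        t = tx("q")
        kept, decisions = exclude_rrna(
            [t], [AlignmentRecord("q", "rRNA_L", e, ident, 0.9, 0.5)]
        )
        assert (kept == []) is removed
        if removed:
            assert decisions[0].reason == "rrna_contamination"

    def test_planted_fixture(self, alignment_fixtures):
        fx, truth = alignment_fixtures
        kept, _ = exclude_rrna(fx.rrna_queries, fx.rrna_alignments)
        assert {t.transcript_id for t in kept} == truth.dedup_kept["rrna"]


class TestStatusFilter:
    def test_removal_vocabulary(self):
        txs = [tx("a"), tx("b"), tx("c")]
        table = {"a": "protein_coding", "c": "lncRNA"}
        kept, decisions = apply_status_filter(txs, table)
        assert [t.transcript_id for t in kept] == ["b", "c"]
        reasons = {d.transcript_id: d.reason for d in decisions}
        assert reasons == {
            "a": "status_removed", "b": "kept", "c": "kept"
        }

    @pytest.mark.parametrize(
        "status", ["pseudogene", "rRNA", "snoRNA", "TE_region", "out_of_date"]
    )
    def test_every_removal_status(self, status):
        kept, _ = apply_status_filter([tx("a")], {"a": status})
        assert kept == []


class TestConservation:
    def test_every_input_gets_one_decision(self, alignment_fixtures):
        fx, _ = alignment_fixtures
        kept, decisions = dedup_against_primary(
            fx.brown_candidates,
            fx.primary,
            fx.brown_alignments,
            "brown",
            flybase_id_map=fx.flybase_id_map,
        )
        assert len(decisions) == len(fx.brown_candidates)
        assert len(kept) + sum(not d.kept for d in decisions) == len(
            fx.brown_candidates
        )
        assert all(d.kept == (d.reason == "kept") for d in decisions)


def test_overlap_groups_reported_not_merged():
    a = tx("a", 1000, start=0, source="flybase")
    b = tx("b", 1000, start=500, source="young")
    c = tx("c", 1000, start=9000, source="brown")
    groups = overlap_groups([a, b, c])
    assert groups == [["a", "b"]]
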