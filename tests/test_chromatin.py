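import pytest

from lnccurate.chromatin import (
    ChromatinAnnotation,
    annotate_gene,
    assign_h3k4me3,
    assign_h3k36me3,
    assign_polII,
    assign_validation_group,
    cage_complete,
    k4k36_call,
    promoter_window,
)
from lnccurate.core import GeneModel, GenomicInterval, TranscriptModel
from lnccurate.io import PeakRecord


def gene(gid="g", start=10_000, end=11_000, strand="+"):
    t = TranscriptModel(
        f"{gid}.t1", gid, "flybase",
        (GenomicInterval("chr2L", start, end, strand),),
    )
    return GeneModel(gid, "lncRNA", (t,))


def peak(start, end, mark, chrom="chr2L"):
    return PeakRecord(GenomicInterval(chrom, start, end), mark, "d")


class TestPromoterWindow:
    def test_plus_strand_window(self):
        w = promoter_window(10_000, "+", "chr2L")
        assert (w.start, w.end) == (9_500, 10_101)
        assert len(w) == 601

    def test_minus_strand_mirror(self):
        w = promoter_window(10_000, "-", "chr2L")
        assert (w.start, w.end) == (9_900, 10_501)
        assert len(w) == 601

    def test_clipped_at_chromosome_start(self):
        w = promoter_window(100, "+", "chr2L")
        assert (w.start, w.end) == (0, 201)

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError):
            promoter_window(100, ".", "chr2L")


class TestH3K4me3:
    def test_peak_in_window(self):
        assert assign_h3k4me3(gene(), [peak(9_600, 9_700, "H3K4me3")]) is True

    def test_half_open_adjacency_misses(self):
        assert assign_h3k4me3(gene(), [peak(9_400, 9_500, "H3K4me3")]) is False

    def test_other_marks_ignored(self):
        assert assign_h3k4me3(gene(), [peak(9_600, 9_700, "PolII")]) is False

    def test_unknown_strand_not_assessable(self):
        g = gene(strand=".")
        assert assign_h3k4me3(g, [peak(9_600, 9_700, "H3K4me3")]) is None

    def test_invariant_under_peak_splitting(self):
        whole = [peak(9_600, 9_700, "H3K4me3")]
        split = [peak(9_600, 9_650, "H3K4me3"), peak(9_650, 9_700, "H3K4me3")]
        assert assign_h3k4me3(gene(), whole) == assign_h3k4me3(gene(), split)


class TestH3K36me3:
    def test_seventy_percent_coverage(self):
        present, cov = assign_h3k36me3(
            gene(), [peak(10_000, 10_700, "H3K36me3")]
        )
        assert present and cov == pytest.approx(0.7)

    def test_no_peaks(self):
        assert assign_h3k36me3(gene(), []) == (False, 0.0)

    def test_full_tiling(self):
        present, cov = assign_h3k36me3(
            gene(), [peak(9_000, 12_000, "H3K36me3")]
        )
        assert present and cov == 1.0


class TestPolII:
    def test_promoter_only_signal(self):
        """A promoter-only Pol II peak counts as present but contributes
        nothing to transcribed-region coverage."""
        present, cov = assign_polII(gene(), [peak(9_600, 9_700, "PolII")])
        assert present and cov == 0.0

    def test_sixty_percent_body_coverage(self):
        present, cov = assign_polII(gene(), [peak(10_000, 10_600, "PolII")])
        assert present and cov == pytest.approx(0.6)

    def test_absent(self):
        assert assign_polII(gene(), []) == (False, 0.0)

    def test_coverage_monotone_under_added_peaks(self):
        g = gene()
        p1 = [peak(10_000, 10_300, "PolII")]
        p2 = p1 + [peak(10_500, 10_800, "PolII")]
        assert assign_polII(g, p2)[1] >= assign_polII(g, p1)[1]


class TestK4K36:
    @pytest.mark.parametrize(
        "k4, k36, expected",
        [(True, True, True), (True, False, False), (False, True, False)],
    )
    def test_conjunction(self, k4, k36, expected):
        ann = ChromatinAnnotation("g", k4, 0.5 if k36 else 0.0, k36, False, 0.0)
        assert k4k36_call(ann) is expected
        assert ann.k4k36 is expected
        if ann.k4k36:
            assert ann.h3k4me3_present and ann.h3k36me3_present


class TestCage:
    TX = TranscriptModel(
        "l", "l", "flybase", (GenomicInterval("chr2L", 1000, 2000, "+"),)
    )

    def test_peak_inside_window(self):
        assert cage_complete(self.TX, [peak(980, 1020, "CAGE")]) is True

    def test_peak_beyond_fifty(self):
        assert cage_complete(self.TX, [peak(1060, 1080, "CAGE")]) is False

    def test_inclusive_boundary(self):
        # the window reaches base 950; a peak containing it counts
        assert cage_complete(self.TX, [peak(940, 951, "CAGE")]) is True
        assert cage_complete(self.TX, [peak(900, 950, "CAGE")]) is False

    def test_minus_strand_uses_three_prime_coordinate_end(self):
        tx_minus = TranscriptModel(
            "l", "l", "flybase", (GenomicInterval("chr2L", 1000, 2000, "-"),)
        )
        assert cage_complete(tx_minus, [peak(1990, 2010, "CAGE")]) is True
        assert cage_complete(tx_minus, [peak(980, 1020, "CAGE")]) is False

    def test_unknown_strand_not_assessable(self):
        tx_u = TranscriptModel(
            "l", "l", "flybase", (GenomicInterval("chr2L", 1000, 2000, "."),)
        )
        assert cage_complete(tx_u, [peak(980, 1020, "CAGE")]) is None

    def test_planted_cage_flags_recovered(self, dataset):
        for t in dataset.lncs:
            if t.strand == ".":
                continue
            assert (
                cage_complete(t, dataset.peaks)
                == dataset.truth.cage_complete[t.transcript_id]
            )


class TestValidationGroups:
    def ann(self, flags):
        k4, k36, pol = flags
        return ChromatinAnnotation(
            "g", k4, 0.7 if k36 else 0.0, k36, pol, 0.6 if pol else 0.0
        )

    @pytest.mark.parametrize(
        "rpkm, flags, expected",
        [
            (15.0, (True, True, True), "G1"),
            (2.0, (True, True, True), "G2"),
            (15.0, (False, False, False), "G3"),
            (2.0, (False, False, False), "G4"),
            (5.0, (True, True, True), "none"),  # between the quartiles
            (15.0, (True, False, True), "none"),  # partial signatures
        ],
    )
    def test_grouping(self, rpkm, flags, expected):
        assert assign_validation_group(rpkm, self.ann(flags)).group == expected

    def test_unexpressed_gene_rejected(self):
        with pytest.raises(ValueError):
            assign_validation_group(0.8, self.ann((True, True, True)))

    def test_planted_groups_recovered(self, dataset):
        got = {}
        for g in dataset.lnc_genes:
            tid = g.transcripts[0].transcript_id
            rpkm = dataset.matrix.at[tid, "polyA"]
            if rpkm <= 1:
                continue
            vg = assign_validation_group(rpkm, annotate_gene(g, dataset.peaks))
            if vg.group != "none":
                got[g.gene_id] = vg.group
        assert got == dataset.truth.validation_group


class TestPlantedSignatures:
    def test_flags_recovered_exactly(self, dataset):
        for g in dataset.lnc_genes:
            ann = annotate_gene(g, dataset.peaks)
            got = (
                bool(ann.h3k4me3_present),
                ann.h3k36me3_present,
                ann.polII_present,
            )
            assert got == dataset.truth.signatures[g.gene_id], g.gene_id

    def test_planted_coverages_near_targets(self, dataset):
        for g in dataset.lnc_genes:
            k4, k36, pol = dataset.truth.signatures[g.gene_id]
            ann = annotate_gene(g, dataset.peaks)
            if k36:
                assert ann.h3k36me3_coverage == pytest.approx(0.7, abs=0.01)
            if pol:
                assert ann.polII_coverage == pytest.approx(0.6, abs=0.01)
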