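import numpy as np
import pytest

from lnccurate.core import ThresholdConfig
from lnccurate.expression import (
    ReadRecord,
    compute_rpkm,
    flag_expressed,
    infer_polya_minus,
    quantify,
    read_fastq,
    rpkm_matrix,
    stage_profile,
    trim_read,
    trim_reads,
    write_fastq,
)


def read(n, quals=None):
    quals = quals if quals is not None else [30] * n
    return ReadRecord("r", "A" * n, tuple(quals))


class TestTrim:
    def test_only_head_trim_for_clean_read(self):
        out = trim_read(read(50))
        assert len(out) == 40

    def test_kept_exactly_at_minimum(self):
        out = trim_read(read(46))
        assert len(out) == 36

    def test_discarded_below_minimum(self):
        assert trim_read(read(45)) is None

    def test_tail_scan_stops_at_first_good_base(self):
        # last three qualities 15, 25, 18: only the trailing 18 goes;
        # the 25 stops the scan and shields the 15
        quals = [30] * 45 + [15, 25, 18]
        out = trim_read(read(48, quals))
        assert len(out) == 37
        assert out.quals[-1] == 25

    def test_quality_equal_to_threshold_is_trimmed(self):
        quals = [30] * 46 + [20]
        out = trim_read(read(47, quals))
        assert len(out) == 36

    def test_never_longer_and_tail_rule_holds(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(5, 120))
            quals = [int(q) for q in rng.integers(0, 45, n)]
            r = read(n, quals)
            out = trim_read(r)
            if out is None:
                continue
            assert len(out) <= n
            assert len(out) >= 36
            assert out.quals[-1] > 20

    def test_batch_counts_discards(self):
        kept, discarded = trim_reads([read(50), read(45)])
        assert (len(kept), discarded) == (1, 1)

    def test_planted_fates_recovered(self, dataset, tmp_path):
        from lnccurate.synthetic import generate_reads

        reads, truth = generate_reads(dataset.config)
        # fates survive a FASTQ round trip too
        p = tmp_path / "r.fastq"
        write_fastq(reads, p)
        back = {r.read_id: r for r in read_fastq(p)}
        for rid, fate in truth.read_fates.items():
            out = trim_read(back[rid])
            got = None if out is None else len(out)
            assert got == fate, rid


class TestRpkm:
    def test_closed_form(self):
        assert compute_rpkm(10, 2000, 5_000_000) == pytest.approx(1.0)
        assert compute_rpkm(0, 2000, 5_000_000) == 0.0
        assert compute_rpkm(50, 1008, 20_000_000) == pytest.approx(
            2.48016, abs=1e-5
        )

    def test_invalid_denominators(self):
        with pytest.raises(ValueError):
            compute_rpkm(1, 0, 1000)
        with pytest.raises(ValueError):
            compute_rpkm(1, 1000, 0)

    def test_linearity(self):
        base = compute_rpkm(10, 1500, 1_000_000)
        assert compute_rpkm(20, 1500, 1_000_000) == pytest.approx(2 * base)
        assert compute_rpkm(10, 1500, 2_000_000) == pytest.approx(base / 2)
        assert compute_rpkm(10, 3000, 1_000_000) == pytest.approx(base / 2)


class TestFlags:
    @pytest.mark.parametrize(
        "rpkm, expressed", [(1.01, True), (1.0, False), (0.0, False)]
    )
    def test_expressed_is_strict(self, rpkm, expressed):
        assert flag_expressed(rpkm, 1.0) is expressed

    @pytest.mark.parametrize(
        "ribo, polya, expected",
        [
            (1.5, 0.0, True),
            (1.5, 0.2, False),  # any poly(A) signal disqualifies
            (0.9, 0.0, False),  # not expressed in ribo-zero
            (1.0, 0.0, False),  # boundary: strictly greater required
        ],
    )
    def test_polya_minus_criterion(self, ribo, polya, expected):
        assert infer_polya_minus(ribo, polya, 1.0) is expected

    def test_polya_minus_implies_expressed(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            ribo = float(rng.uniform(0, 3))
            polya = float(rng.choice([0.0, rng.uniform(0, 2)]))
            if infer_polya_minus(ribo, polya, 1.0):
                assert flag_expressed(ribo, 1.0)

    def test_planted_polya_minus_recovered(self, dataset):
        m = dataset.matrix
        inferred = {
            tid
            for tid in m.index
            if infer_polya_minus(m.at[tid, "ribozero"], m.at[tid, "polyA"], 1.0)
        }
        assert inferred == dataset.truth.polya_minus


class TestQuantify:
    def test_missing_total_or_length_rejected(self):
        with pytest.raises(ValueError, match="library"):
            quantify({("t", "lib"): 1}, {}, {"t": 100})
        with pytest.raises(ValueError, match="transcript"):
            quantify({("t", "lib"): 1}, {"lib": 100}, {})

    def test_rpkm_zero_iff_count_zero(self, dataset):
        lengths = {t.transcript_id: t.length for t in dataset.lncs}
        sub = {
            k: v for k, v in dataset.counts.items() if k[0] in lengths
        }
        for rec in quantify(sub, dataset.totals, lengths):
            assert (rec.rpkm == 0) == (rec.read_count == 0)


class TestStageProfile:
    def test_mean_and_expressed_count(self):
        import pandas as pd

        m = pd.DataFrame(
            {"stage01": [0.0, 4.0]}, index=["l1", "l2"]
        )
        prof = stage_profile(m, {"l1": "lncRNA", "l2": "lncRNA"})
        row = prof.loc[("stage01", "lncRNA")]
        assert row["mean_rpkm"] == pytest.approx(2.0)
        assert row["n_expressed"] == 1

    def test_missing_biotype_rejected(self):
        import pandas as pd

        m = pd.DataFrame({"s": [1.0]}, index=["l1"])
        with pytest.raises(ValueError):
            stage_profile(m, {})

    def test_fold_ratio_recovered_within_three_se(self, dataset):
        """The configured 8-fold mRNA:lncRNA mean expression ratio is
        recovered from the negative-binomial stage counts."""
        stages = [c for c in dataset.matrix.columns if c.startswith("stage")]
        biotype = {t.transcript_id: "lncRNA" for t in dataset.lncs}
        biotype.update(
            {
                g.transcripts[0].transcript_id: "mRNA"
                for g in dataset.genes
            }
        )
        prof = stage_profile(dataset.matrix[stages], biotype)
        mr = prof.xs("mRNA", level="biotype")["mean_rpkm"]
        ln = prof.xs("lncRNA", level="biotype")["mean_rpkm"]
        x = dataset.matrix[stages].loc[
            [t for t, b in biotype.items() if b == "mRNA"]
        ].to_numpy().ravel()
        y = dataset.matrix[stages].loc[
            [t for t, b in biotype.items() if b == "lncRNA"]
        ].to_numpy().ravel()
        ratio = x.mean() / y.mean()
        # delta-method standard error of a ratio of independent means
        se = ratio * np.sqrt(
            x.var(ddof=1) / (len(x) * x.mean() ** 2)
            + y.var(ddof=1) / (len(y) * y.mean() ** 2)
        )
        target = dataset.config.mrna_to_lnc_expression_ratio
        assert abs(ratio - target) <= 3 * se
        # the per-stage profile sees the same effect direction everywhere
        assert (mr.to_numpy() > ln.to_numpy()).all()
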