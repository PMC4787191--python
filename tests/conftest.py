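from dataclasses import dataclass

import pytest

from lnccurate import synthetic as S
from lnccurate.core import GeneModel, TranscriptModel, UNKNOWN
from lnccurate.expression import quantify, rpkm_matrix


@dataclass
class Dataset:
    config: S.SimulationConfig
    genes: list
    lncs: list
    peaks: list
    counts: dict
    totals: dict
    truth: S.GroundTruth
    matrix: object  # transcripts x libraries RPKM frame

    @property
    def lnc_genes(self):
        return S.lnc_genes(self.lncs)


@pytest.fixture(scope="session")
def dataset() -> Dataset:
    """One full synthetic dataset with planted truth, shared per session."""
    config = S.SimulationConfig(seed=7)
    genes, truth = S.generate_annotation(config)
    lncs, truth = S.generate_lncrnas(config, genes, truth)
    peaks, truth = S.generate_peaks(config, genes, lncs, truth)
    counts, totals, truth = S.generate_expression(config, genes, lncs, truth)
    lengths = {t.transcript_id: t.length for t in lncs}
    lengths.update(
        {g.transcripts[0].transcript_id: g.transcripts[0].length for g in genes}
    )
    matrix = rpkm_matrix(quantify(counts, totals, lengths))
    return Dataset(config, genes, lncs, peaks, counts, totals, truth, matrix)


@pytest.fixture(scope="session")
def alignment_fixtures():
    return S.generate_alignment_fixtures(S.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def discovery_fixture(dataset):
    return S.generate_discovery_fixture(dataset.config, dataset.genes)


def brute_force_class(lnc: TranscriptModel, coding_genes) -> str:
    """Per-base oracle classifier, independent of the interval arithmetic.

    Labels every base by set membership: exon contact wins, then gene-span
    contact, else intergenic; the anchor is the gene with the most shared
    bases (smallest id on ties) and fixes sense/antisense.
    """
    if lnc.strand == UNKNOWN:
        return "unknown"
    lnc_exon_bases = {b for e in lnc.exons for b in range(e.start, e.end)}
    lnc_span_bases = set(range(lnc.span.start, lnc.span.end))
    exon_by_gene: dict[str, int] = {}
    span_by_gene: dict[str, int] = {}
    strand_of: dict[str, str] = {}
    for g in coding_genes:
        strand_of[g.gene_id] = g.strand
        if g.chrom != lnc.chrom:
            continue
        gene_exon_bases = {
            b for e in g.exons for b in range(e.start, e.end)
        }
        n = len(lnc_exon_bases & gene_exon_bases)
        if n:
            exon_by_gene[g.gene_id] = n
        n = len(lnc_span_bases & set(range(g.span.start, g.span.end)))
        if n:
            span_by_gene[g.gene_id] = n

    def pick(d):
        return min(d, key=lambda k: (-d[k], k))

    if exon_by_gene:
        gid = pick(exon_by_gene)
        rel = "sense" if strand_of[gid] == lnc.strand else "antisense"
        return f"exonic_{rel}"
    if span_by_gene:
        gid = pick(span_by_gene)
        rel = "sense" if strand_of[gid] == lnc.strand else "antisense"
        return f"intronic_{rel}"
    return "intergenic"
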