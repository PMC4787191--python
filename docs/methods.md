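# Methods

## Coordinate model

All genomic reasoning happens on 0-based half-open intervals; GTF's
1-based closed convention is converted at the I/O boundary, BED is native.
Strand is `+`, `-` or `.` (unknown), and unknown is never coerced:
direction-unknown transcripts are carried through every table as their own
category, are classed `unknown` regardless of location, and are excluded
from promoter-anchored assessments (H3K4me3, CAGE) as *not assessable*,
which is distinct from an assessed absence.

Transcript spans and lengths are always recomputed from the exon chain;
any span feature in an input file is ignored, so there is a single source
of truth for the length `L` that drives length filters and RPKM.

## Redundancy rules

Only alignments with E-value below the ceiling (default 1e-10) count as
evidence. Three source-specific rules are implemented:

* **flybase_ucsc** — remove on identical loci, or on coverage ≥ 50 % of
  the *candidate's* length ("the transcript length" reads as the
  transcript under test).
* **brown** — remove when the candidate carries an already accepted
  FlyBase ID, or when coverage exceeds 50 % of *either* transcript's
  length (the max of both fractions), unless the candidate has ≥ 2 exons
  and its exon count differs from the matched transcript's — structurally
  distinct isoforms are retained.
* **young_vs_brown** — remove only on identical loci or ≥ 90 % coverage of
  the candidate's own length (the rule's denominator is not stated
  anywhere authoritative; the candidate's length is used, consistent with
  the 50 % rule).

"Same loci" is read strictly: identical chromosome, strand, span and exon
boundary chain. When no alignments are supplied, a coordinate fallback
derives the same fractions from genomic exon-union intersections and
computes same-loci structurally; decisions carry a provenance flag so the
two evidence routes are distinguishable downstream. Candidates are judged
independently against the full primary set, which makes the procedure
order-independent and idempotent; alignments whose query is not among the
current candidates are ignored rather than rejected, precisely so that
re-running the survivors against the same evidence removes nothing.

Ribosomal exclusion requires both conditions jointly: E < 1e-10 **and**
identity > 99 % (strict inequalities on both).

## Discovery funnel

Stage order is fixed: intergenic detection → length ≥ 200 bp → coding
potential → rRNA → read support → sense overlap. Intergenicity is
strand-blind (exon overlap with any reference transcript span on either
strand disqualifies), whereas the final sense-overlap filter tests
exon–exon overlap on the same strand only — a transcript inside a coding
intron or antisense to a coding exon is a legitimate catalogue class and
must survive. Probability-based coding scores remove at value ≥ cutoff
(0.39); an id absent from the remap count table counts as unsupported.
Each stage emits `(in, removed, out)` and the report constructor enforces
`out = in − removed` and stage chaining, so bookkeeping errors fail fast
rather than propagate.

## Classification

Precedence is exonic > intronic > intergenic: exon contact with any coding
gene wins over intron containment in another. "Intronic" covers any
gene-span overlap without exon contact (≥ 1 bp), not only full
containment — partial-overlap geometries are undefined in the source
material and are resolved toward intronic. The anchor is the gene with
maximal overlap (exon-union bp for exonic, span bp for intronic), ties
broken by lexicographically smallest gene id for determinism. Coding genes
must have known strand; multi-isoform genes are assessed on their gene
span (min start, max end over isoforms) and pooled exons.

## Expression

Trimming: the first 10 bases go unconditionally (random-primer artefacts);
3'-terminal bases are removed while quality ≤ 20, stopping at the first
base above it (a single high-quality base shields everything 5' of it);
reads shorter than 36 bp afterwards are discarded. Qualities are phred+33.

RPKM uses the full exon-union length and a library-wide mapped-read total
supplied in the count-table header — never re-derived from the transcript
subset present. This deterministic formula replaces effective-length-aware
EM quantification; numeric parity with estimates produced by such
quantifiers is therefore not expected and not claimed. "Expressed" is
strict (`RPKM > 1`). The poly(A)-minus call demands a literal zero in the
poly(A) library (count 0, hence RPKM 0, no epsilon): the ribo-zero library
also contains polyadenylated species, so any poly(A) signal disqualifies.

## Chromatin signatures

The promoter window covers signed transcription-direction distances −500
to +100 bp around the gene-level TSS (5'-most isoform start), inclusive —
601 bp unless clipped at the chromosome start. All datasets of one mark
are unioned before assignment: any-stage presence counts, mirroring pooled
multi-stage peak collections that are not stage-matched to the expression
data. H3K36me3 coverage is computed over the transcribed region, TSS to
TES including introns (the mark extends across gene bodies); presence is
any nonzero coverage. Pol II presence considers promoter plus body, but
its coverage is reported over the body only, so a promoter-only signal is
(present, 0.0). The K4–K36 call is the conjunction of promoter H3K4me3 and
body H3K36me3. The CAGE window around the 5' base is inclusive at both
ends (±50 bp). Validation groups G1–G4 cross all-three/none-of-three
signature status with expression above the 3rd (12.92 RPKM) or below the
1st (2.78 RPKM) quartile; genes between quartiles or with partial
signatures belong to no group, and grouping a non-expressed gene
(RPKM ≤ 1) is an error. A gene whose promoter cannot be assessed (unknown
strand) is never "none of three" — unassessable is not absent.

## Reporting

−ΔCt = Ct(reference) − mean Ct(replicates); the reference gene's Ct is an
explicit input because no normalizer can be assumed. Detection is
−ΔCt ≥ cutoff. Percentages are rounded half-up to two decimals; per-class
length dispersion uses the sample (n−1) standard deviation.

## Synthetic data

The generator emulates the study conditions at desk scale: one toy
chromosome (2 Mb) with 30 disjoint three-exon coding genes on alternating
strands (mature length centred on 2869 bp, introns ≥ 2.6 kb, gaps ≥ 4 kb),
and 41 lncRNAs realizing every positional class with planted labels —
20 intergenic, 7 exonic-antisense, 3 exonic-sense, 5 intronic-antisense,
3 intronic-sense, 3 strand-unknown, proportions echoing the curated
catalogue (intergenic dominant, antisense over sense in both overlap
classes). LncRNA lengths centre on 1008 bp and exon counts put 94 % of
mass on 1–3 exons, over half single-exon.

Known-strand lncRNA genes cycle through all eight presence patterns of
(H3K4me3, H3K36me3, Pol II); planted marks realize ~70 % body coverage for
H3K36me3 and ~60 % for Pol II, the scales reported for genes carrying
those marks. Decoy peaks of every mark are placed in unoccupied gaps.
Placement uses wide padding (≥ 1.2–1.8 kb between planted features) so
promoter and CAGE windows of neighbouring plants cannot touch — planted
flags are therefore recoverable exactly, by construction.

Counts are negative-binomial (variance μ + φμ², φ = 0.3 by default, a
typical bulk RNA-seq overdispersion) with mean proportional to transcript
length times a biotype level; the mRNA level is 8× the lncRNA level, so
the expected RPKM ratio equals the configured fold change. Brain libraries
use fixed declared totals (5 M poly(A), 8 M ribo-zero); 30 developmental
stages use 4 M each. Planted poly(A)-minus transcripts (13 % of lncRNAs,
the catalogue's observed share among brain-expressed transcripts) get zero
poly(A) counts and ribo-zero counts well above the expressed threshold;
all other transcripts keep at least one poly(A) read so the stringent zero
criterion identifies exactly the planted set. Validation-group plants pin
poly(A) counts to RPKM targets inside the high/low quartile bands.

FASTQ fixtures bracket the trimming boundaries (kept at exactly 36 bp,
discarded at 35, tail-scan stop at a shielding high-quality base, boundary
quality equal to the threshold, fully low-quality tail), plus random reads
with decaying 3' tails. Alignment fixtures realize every dedup branch and
the three rRNA threshold corners. The discovery fixture plants one fate
per funnel stage: 42 assembled structures per library (identical across
the two libraries, collapsing in the union), of which 20 survive.

Determinism: every fixture draws from a substream keyed by
`(seed, fixture-name)` (CRC-32 of the name, masked below 2³¹), so one seed
fixes every emitted byte and adding a fixture never perturbs the others.

### What the generator does not emulate

No sequence-level realism (no codon structure, GC bias, mappability), no
aligner-ready reads, no isoform mixtures within a gene, no stage-matched
chromatin/expression correlation, and planted features are deliberately
non-interfering, whereas real loci overlap and real peaks straddle
neighbouring genes. Passing plant-recovery tests therefore demonstrates
that the decision rules are implemented exactly as specified — not that
the rules are robust to ambiguous real-data geometries, which the
catalogue's own caveats (overlapping multi-source transcripts needing
manual review) acknowledge.

## Problem sizes and runtime

Defaults were chosen for second-scale runs: 30 coding genes, 41 lncRNAs,
30 stages, ~2,200 count cells, 65 reads, 1000 random transcripts for the
per-base classification oracle. The full test suite and the acceptance
script each complete in well under a minute on one CPU.

## Known limitations

* RPKM is count-based on full transcript length; effective-length and
  multi-mapping corrections are out of scope, so absolute RPKM values are
  not comparable to EM-based estimates.
* The 725→591 step of the published funnel switches counting units
  (transcripts to genes); this implementation counts transcripts at every
  stage and makes no gene/transcript conversion.
* Overlapping curated transcripts from different sources are reported as
  overlap groups, never merged; merging requires manual review.
* The Pol II gene-fraction denominator is ambiguous between all curated
  genes and the direction-assessable subset; outputs report counts so
  either fraction can be formed.
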