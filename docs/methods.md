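# Methods notes

This note records the models and decision rules the package implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the choices made where the design was genuinely open.

## Variant handling

Somatic SNVs come from two callers' VCFs and are merged by union on the key
(chrom, pos, ref, alt): a variant reported by at least one caller survives.
Where both callers report the same variant, the merged record keeps the
union of caller labels and the **maximum** of the two tumor allele fractions.
The downstream filter is a one-sided threshold (MAF ≥ 25%), so the maximum is
the permissive choice and keeps the merge commutative and idempotent; no
published reconciliation rule exists for this case. Conflicting RNA read
counts at the same locus are treated as an input error, not silently
resolved.

"MAF" throughout is the tumor variant-allele fraction in percent. The term
is used inconsistently in the field (sometimes "minor allele frequency");
this package reads it from the VCF tumor AF field (FORMAT `AF` by default,
falling back to INFO, key configurable) and stores it on a 0–100 scale.

Coding effects are computed directly from transcript CDS blocks and the
genome: locate the variant in a block, map to the CDS index (reverse
complemented on minus-strand transcripts), substitute within the codon, and
translate both codons with the standard table. Every transcript containing
the position is annotated; peptide design then keeps one effect per gene,
preferring the longest CDS (a deterministic tie-break the data does not
dictate). Coordinates are 1-based at the interfaces (VCF, GFF3, protein
positions) and 0-based half-open internally.

RNA mutant/wild-type read counts are attached from a locus-keyed TSV rather
than recomputed from alignments — read-level pileup is out of scope, and the
funnel only consumes the counts. A variant missing from the table gets
(0, 0) with a warning, which makes it fail the RNA stage rather than crash.

## Peptide design

One amino-acid change plus 12 wild-type residues on each side gives a 25-mer
that carries the maximum number of potential class-I and class-II epitopes.
Windows are clipped at the protein termini (a mutation 7 residues from the
N-terminus yields a 19-mer with flanks 6/12) and never padded. Mutations on
the same protein within 12 residues of one another merge into a single
peptide; the cap rule keeps the full 12-residue flank downstream of the last
mutation and gives the remainder (25 − span − 12) upstream of the first.
This reproduces the published double-mutation window with 9/12 flanks. The
alternative reading — that the shortened upstream flank reflects truncation
at the protein's N-terminus — cannot be excluded without the source protein
sequence; the budget rule was chosen because it is well defined for every
input.

Peptides shorter than 8 residues after clipping are flagged (`too_short`,
below the class-I presentation minimum) but kept; discarding is a funnel
decision. The `NeoantigenPeptide` type itself does not impose the 25-residue
cap — the designer does (`max_len=25`) — because published fixture peptides
(the MC38 set, which predates the 25-mer rule, and one CT26 row as printed)
exceed it.

Report notation is mutant-first, `[mut/wt]`, and both residues are stored
explicitly, so notation ambiguity cannot corrupt data. The packaged MC38
table is normalized to this convention (the source prints wild-type first).

## Selection funnel

The funnel applies, in order: MHC binding, MAF, RNA expression. Binding
passes when IC50 ≤ 500 nM (class I) **or** percentile rank ≤ 1 (class II).
The OR is anchored to the data: the published selected set contains records
passing only class II (IC50 ≈ 13,000 nM, rank 0.05) and only class I (IC50
41.5 nM, rank 48.7), which a literal AND would reject. All boundaries are
inclusive exactly as printed (≤ 500, ≤ 1, ≥ 25%, ≥ 1 read). The stage order
affects only the `rejection_stage` label, never the selected set, since the
criteria are independent; labels follow the published listing order.

Binding prediction is pluggable. The normal route is a precomputed score
table (external consensus predictors are consumed, not reimplemented). The
built-in mock predictor exists for pipeline testing: it hashes the peptide's
k-mers with a seed and maps the result to a log-uniform pseudo-IC50 on
[1, 5·10⁴] nM and a uniform pseudo-rank on [0, 100] — deterministic,
reproducible, and deliberately ignorant of allele identity. MHC alleles are
configuration, not model: the mock ignores them and a score table encodes
whatever alleles produced it.

## Construct assembly

Selected peptides are concatenated head to tail in the given order, with no
linkers and no junction-epitope screening — plain joining is the published
design, and the input order is the contract (the published segment order is
not stated). Back-translation takes the most-frequent codon per residue from
a codon-usage table; the packaged default carries approximate mouse
frequencies, and frequency ties break on the lexicographically smallest
codon so output is deterministic. The tested contract is the translation
round trip (`translate(back_translate(p)) == p`) and determinism, not the
frequency values themselves.

## Assay decision rules

**ELISpot.** A response is positive when (i) the ConA well produced IFN-γ
spots, (ii) antigen wells reach 3× the DMSO background, and (iii) at least
30 specific SFC per 10⁶ splenocytes remain after background subtraction.
"Specific" is antigen − DMSO floored at zero (the term is used without a
formula in the assay literature). Per-well counts are normalized to SFC/10⁶,
replicate wells averaged within each plating density, then the two densities
averaged — the assay layout (duplicates at two densities) is published, the
reconciliation is not, and the mean is the neutral choice. ConA positivity
is threshold-configurable (default 50 SFC/10⁶) since no numeric criterion is
published.

**Tumor courses.** Volume is 0.5 × length × width² with length the longer
caliper dimension (entries are auto-sorted). A course is `endpoint` when any
volume exceeds 2000 mm³ (the animal is killed, so endpoint takes precedence
over any later value), `responder` on complete regression (volume 0 at the
last observation), otherwise `non_responder`. Partial-shrinkage categories
are deliberately not invented.

## Expression analytics

TPM divides each gene's count by its length in kb and normalizes the rates
to 10⁶ per sample. Genes are dropped when total count < 10 **or** best-sample
TPM < 1; the published phrasing is ambiguous between OR and AND, so the
stricter reading is the default with the looser one available
(`rule="both"`). BH adjustment is the standard step-up (via statsmodels),
applied per method.

The consensus vote retains a gene when ≥ 3 of the 4 method tables flag it
(adjusted p ≤ 0.05, inclusive — printed both as ≤ and < in the source
material, inclusive chosen and configurable) and the absolute **median**
log2 fold change across all four methods is strictly > 1. The median is
taken over all four methods, not only the flagging ones (the source does not
say; all-four is the better-defined statistic and matches the "median
log2 FC" label). The four DE methods themselves are not reimplemented —
synthetic per-method tables exercise the consensus machinery.

Enrichment is the upper-tail hypergeometric on (universe, term, query) with
Bonferroni over tested terms; the universe is the filtered gene set, not the
whole annotation. The two published significance cutoffs (0.05 and 0.01) are
exposed as the caller's reporting threshold. Pathway coverage (100·k/K) uses
an inclusive ≥ 40% reporting rule, and two response groups are compared per
term with a two-sided Fisher exact test on the modulated/not 2×2 table.

## TCR repertoire

Clonotypes are unique CDR3 sequences — nucleotide level when available,
amino-acid fallback, configurable — with duplicate CDR3s collapsed by
summing reads and the chain inferred from the V-hit column. DE50 sorts
counts descending (ties broken lexicographically by sequence), takes the
smallest prefix whose cumulative reads reach at least half the total
(inclusive at exactly 50%), and reports 100·k/n. The denominator for "half
the reads" is the table's total clonotype reads; whether the original
analyses used all TCR-mapped reads instead is not recoverable from clonotype
exports, so this is a documented approximation. DE50 is invariant to row
order and count rescaling, and decreases with repertoire skew.

## Synthetic data

One user seed drives all generators through named `SeedSequence` substreams
(mutanome/repertoire/elispot/de), so each module regenerates independently
yet reproducibly; fixed seed means byte-identical files.

The mutanome generator emulates the *structure* of tumor/normal exome +
RNA-seq derived inputs, not their biology: random CDSs (60–200 codons, 1–2
blocks, both strands) on one synthetic chromosome; 31 planted SNVs (the size
of the published selected set), one per transcript, each missense by
construction; 20 planted to pass all three funnel stages, the rest failing a
random non-empty subset. Stage values are drawn on the correct side of each
threshold (MAF uniform 30–90 vs 5–24; mutated reads 1–150 vs 0; binding
log-uniform IC50 and uniform rank drawn per the OR rule), so planted-truth
recovery is exact by design and any deviation is an implementation defect —
that is the point of the test. Caller VCFs are Bernoulli subsets (default
sensitivities 0.9/0.8) with union coverage forced. Binding tables are keyed
by peptide id (gene_wtPOSmut) — generated directly rather than from a
sequence model, because the funnel consumes only thresholds.

What the generators do **not** emulate: sequencing noise and alignment
artifacts, mutational signatures, germline contamination, linkage between
expression and MAF, real MHC binding landscapes, or inter-method correlation
structure in DE tables beyond the planted effects. Passing recovery tests
therefore validates the decision rules, not the upstream callers or
predictors.

Repertoires draw multinomial reads over Zipf(s) weights with one guaranteed
read per clonotype (n = 200, depth 40,000 in the shipped checks — large
enough that the even-repertoire DE50 sits within a couple of points of the
analytic 50%). ELISpot plates are Poisson with planted positives at 300
SFC/10⁶ over a 5 SFC/10⁶ background, duplicates at two densities. DE tables
plant 50/1000 true genes at |log2FC| ≈ 2 with small p-values forced in ≥ 3
methods; nulls get uniform p and N(0, 0.2) fold-change noise, which the
magnitude rule suppresses essentially completely.

## Numerical details and limitations

* VCF FORMAT floats return as float32; MAF is rounded to 4 decimals on read.
* Funnel thresholds compare with IEEE `<=`/`>=` on the printed values; no
  epsilon is applied.
* `enrich` does not test terms with zero genes in the universe, and the
  Bonferroni factor counts only tested terms.
* Fisher and hypergeometric p-values come from scipy; the test suite checks
  them against exhaustive enumeration oracles on small instances.
* Indels, MNVs, splice/UTR effects, frameshift and fusion neoantigens are
  out of scope; only biallelic SNVs are considered, and multi-allelic
  records are split before merging.
* The pipeline is desk-scale by design: problem sizes in the shipped tests
  and acceptance script (≤ 40 transcripts, 1000-gene DE tables, 5 seeds) are
  chosen to exercise every rule deterministically, not to reproduce
  cohort-scale counts, which would require the original sequencing data.
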