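# neovax

Desk-scale tooling for multi-neoantigen cancer-vaccine design and the
response analytics that go with it, modeled on the computational workflow of
adenoviral polyepitope vaccine studies in mouse tumor models (CT26, MC38).

## What it does

**Neoantigen selection.** Somatic SNVs from two variant callers are read from
VCF, union-merged on (chrom, pos, ref, alt), and annotated at codon level
against transcript models to retain missense changes. Each amino-acid change
is flanked by 12 wild-type residues on both sides to give a 25-mer peptide
(clipped at protein termini, never padded; mutations within 12 residues of
each other merge into one peptide). Candidates then pass a sequential
prioritization funnel:

1. **MHC binding** — predicted class-I IC50 ≤ 500 nM *or* class-II
   percentile rank ≤ 1 (an OR: the published selected sets contain peptides
   passing only one class);
2. **tumor allele fraction** — MAF ≥ 25%;
3. **RNA expression** — ≥ 1 mutated RNA read.

Selected peptides are joined head to tail (no linkers) into one artificial
protein and back-translated with the most-frequent mouse codon per residue,
with a GFF3 feature per segment.

**Response analytics.** IFN-γ ELISpot positivity (ConA validity, ≥ 3× the
DMSO background, ≥ 30 specific SFC/10⁶ splenocytes), caliper tumor volume
(0.5 × L × W², L the longer dimension) with endpoint (> 2000 mm³) and
complete-regression calls, TPM with gene filtering, per-method
Benjamini–Hochberg adjustment and a 3-of-4 consensus DEG vote
(|median log2FC| > 1), hypergeometric gene-set enrichment with Bonferroni,
per-pathway coverage comparison by Fisher exact test, and TCR-β repertoire
statistics (unique CDR3 clonotypes and DE50 diversity evenness — the minimum
percentage of clonotypes accounting for half the reads).

**Synthetic data.** Every input the pipeline consumes can be generated with
planted ground truth (`neovax.simulate`): mutanome bundles whose SNVs are
missense by construction and carry pass/fail labels for each funnel stage,
Zipf-distributed clonotype repertoires, Poisson ELISpot plates, and
four-method DE tables with planted true positives. One seed drives named
substreams; identical seeds give byte-identical files.

The package also ships the two published neoantigen tables as fixtures
(`neovax.datasets`): the 31-record CT26 set and the 7-record MC38 set.

## Worked example

```python
from neovax import datasets, simulate, pipeline
from neovax.funnel import TableBindingPredictor, apply_funnel, selected
from neovax.constructs import assemble, with_dna

# published CT26 table through the funnel and into a construct
done = apply_funnel(datasets.ct26_candidates())
peps = [c.peptide for c in selected(done)]
construct = with_dna(assemble(peps, name="ct26_31"))
print(len(peps), construct.n_segments, len(construct.protein_sequence))
# 31 31 768

# synthetic mutanome, end to end
cfg = simulate.SimulationConfig(seed=1)
bundle = simulate.simulate_mutanome(cfg, "out/mutanome")
res = pipeline.select_neoantigens(
    bundle.vcf_a, bundle.vcf_b, bundle.transcripts_gff3, bundle.genome_fasta,
    bundle.rna_counts_tsv, TableBindingPredictor.from_tsv(bundle.binding_tsv),
    caller_labels=cfg.caller_labels,
)
truth = bundle.truth
print(len(res.candidates), len(res.selected),
      {c.peptide.id for c in res.selected} == set(truth.loc[truth.pass_all, "peptide_id"]))
# 31 20 True
```

All 31 published CT26 records pass the funnel (several only via one MHC
class), assemble into a 31-segment, 768-residue polyepitope, and on the
synthetic mutanome the funnel recovers exactly the 20 planted pass-all SNVs
out of 31.

A `neovax` CLI wraps the same functions: `simulate`, `select`, `design`,
`elispot`, `volume`, `deg`, `enrich`, `tcr` (see `neovax --help`).

## Layout

| module | contents |
| --- | --- |
| `neovax.variants` | VCF ingestion, union-merge, codon-level annotation |
| `neovax.peptides` | 25-mer window design, grouping, bracket notation |
| `neovax.funnel` | binding predictors, funnel, report |
| `neovax.constructs` | head-to-tail assembly, back-translation, FASTA/GFF3 |
| `neovax.immuno` | ELISpot calls, tumor volumes, course classification |
| `neovax.omics` | TPM, filters, BH, consensus DEG, enrichment, Fisher |
| `neovax.repertoire` | clonotype tables, DE50 |
| `neovax.simulate` | seeded generators with planted truth |
| `neovax.datasets` | packaged published tables, mouse codon usage |

See `docs/methods.md` for the modeling choices and their rationale.
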