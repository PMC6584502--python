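"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here, so each stage is
testable with no external download: a mutanome bundle (genome FASTA,
transcript GFF3, two caller VCFs, RNA-count and binding tables, plus a truth
table of planted funnel labels), Zipf-distributed clonotype repertoires,
Poisson ELISpot plates, and four-method differential-expression tables with
planted true positives.

A single user seed governs everything through named substreams (one
``numpy.random.SeedSequence`` child per generator), so modules can be
regenerated independently yet reproducibly: the same seed yields
byte-identical output files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

_SUBSTREAMS = {
    "mutanome": 0,
    "repertoire": 1,
    "elispot": 2,
    "de": 3,
}

_NONSTOP_CODONS = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if str(Seq("".join(c)).translate()) != "*"
]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG of the master seed (documented substream scheme)."""
    if name not in _SUBSTREAMS:
        raise KeyError(f"unknown substream {name!r}")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_SUBSTREAMS[name],))
    )


# ---------------------------------------------------------------------------
# Mutanome bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults for the synthetic mutanome.

    31 planted somatic SNVs echo the size of the published selected set; 20
    of them are planted to pass all three funnel stages.  Caller
    sensitivities emulate two imperfect variant callers whose union covers
    the truth.
    """

    seed: int = 0
    n_transcripts: int = 40
    cds_codons: tuple = (60, 200)
    n_somatic_snvs: int = 31
    n_pass_all: int = 20
    caller_sensitivity: tuple = (0.9, 0.8)
    caller_labels: tuple = ("mutect", "varscan2")
    intergenic_gap: tuple = (120, 400)

    def __post_init__(self) -> None:
        if self.n_pass_all > self.n_somatic_snvs:
            raise ValueError("n_pass_all cannot exceed n_somatic_snvs")
        if self.n_somatic_snvs > self.n_transcripts:
            raise ValueError(
                "planted SNVs exceed CDS capacity (one per transcript): "
                f"{self.n_somatic_snvs} > {self.n_transcripts}"
            )


@dataclass(frozen=True)
class MutanomeBundle:
    """Paths of one generated mutanome plus its planted truth table."""

    genome_fasta: Path
    transcripts_gff3: Path
    vcf_a: Path
    vcf_b: Path
    rna_counts_tsv: Path
    binding_tsv: Path
    truth_tsv: Path

    @property
    def truth(self) -> pd.DataFrame:
        return pd.read_csv(self.truth_tsv, sep="\t", dtype={"chrom": str})


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(_NONSTOP_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _plant_missense(rng: np.random.Generator, cds: str) -> Optional[tuple]:
    """Pick (cds_index, ref, alt, wt_aa, mut_aa) giving a missense change."""
    n_codons = len(cds) // 3
    for codon_i in rng.permutation(np.arange(1, n_codons - 1)):
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        wt_aa = str(Seq(codon).translate())
        choices = [(w, b) for w in range(3) for b in "ACGT" if b != codon[w]]
        rng.shuffle(choices)
        for within, base in choices:
            mut_codon = codon[:within] + base + codon[within + 1 :]
            mut_aa = str(Seq(mut_codon).translate())
            if mut_aa not in ("*", wt_aa):
                return codon_i * 3 + within, codon[within], base, wt_aa, mut_aa
    return None


def simulate_mutanome(config: SimulationConfig, outdir) -> MutanomeBundle:
    """Generate a complete mutanome input bundle with planted funnel labels.

    Every planted SNV is missense by construction.  Each caller's VCF holds a
    Bernoulli(sensitivity) subset of the truth; an SNV drawn by neither
    caller is assigned to the first so the union always covers the truth.
    Binding scores are drawn directly (log-uniform IC50 on [1, 5e4] nM, rank
    on [0, 100]) on either side of the MHC OR rule according to the planted
    label; MAF and RNA mutated-read draws likewise respect their stage labels
    exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = substream(config.seed, "mutanome")

    # --- transcripts laid head to tail on one chromosome, random strand ----
    chrom = "chr1"
    genome_parts: List[str] = []
    cursor = 0  # 0-based genome length so far
    transcripts = []  # (tid, gene, strand, blocks, cds)
    for i in range(config.n_transcripts):
        gap = int(rng.integers(*config.intergenic_gap))
        genome_parts.append(_random_seq(rng, gap))
        cursor += gap
        n_codons = int(rng.integers(*config.cds_codons))
        cds = _random_cds(rng, n_codons)
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = cds if strand == "+" else cds.translate(_COMPLEMENT)[::-1]
        # 1-2 CDS blocks: optionally split by a small intron
        if rng.random() < 0.5 and len(genomic) > 60:
            cut = int(rng.integers(20, len(genomic) - 20))
            intron = _random_seq(rng, int(rng.integers(40, 80)))
            block1 = (cursor + 1, cursor + cut)
            block2_start = cursor + cut + len(intron) + 1
            block2 = (block2_start, block2_start + (len(genomic) - cut) - 1)
            genome_parts.extend([genomic[:cut], intron, genomic[cut:]])
            cursor = block2[1]
            blocks = (block1, block2)
        else:
            blocks = ((cursor + 1, cursor + len(genomic)),)
            genome_parts.append(genomic)
            cursor += len(genomic)
        transcripts.append((f"tx{i:03d}", f"Gene{i:03d}", strand, blocks, cds))
    genome_parts.append(_random_seq(rng, int(rng.integers(*config.intergenic_gap))))
    genome = "".join(genome_parts)

    # --- plant one missense SNV in each of n_somatic_snvs transcripts ------
    chosen = rng.choice(len(transcripts), size=config.n_somatic_snvs, replace=False)
    labels = np.zeros(config.n_somatic_snvs, dtype=bool)
    labels[: config.n_pass_all] = True
    rng.shuffle(labels)

    truth_rows = []
    for snv_i, t_i in enumerate(sorted(chosen)):
        tid, gene, strand, blocks, cds = transcripts[t_i]
        planted = _plant_missense(rng, cds)
        if planted is None:  # pragma: no cover - virtually impossible
            raise RuntimeError(f"no missense substitution available in {tid}")
        cds_idx, cds_ref, cds_alt, wt_aa, mut_aa = planted
        pos, ref, alt = _cds_index_to_genomic(blocks, strand, cds_idx, cds_ref, cds_alt)
        assert genome[pos - 1] == ref

        pass_all = bool(labels[snv_i])
        if pass_all:
            maf_pass, rna_pass, mhc_pass = True, True, True
        else:
            fails = rng.random(3) < 0.5
            if not fails.any():
                fails[int(rng.integers(3))] = True
            mhc_pass, maf_pass, rna_pass = (not f for f in fails)
        maf = float(rng.uniform(30, 90)) if maf_pass else float(rng.uniform(5, 24))
        mut_reads = int(rng.integers(1, 150)) if rna_pass else 0
        wt_reads = int(rng.integers(0, 200))
        if mhc_pass:
            route = rng.integers(3)  # ic50 only / rank only / both
            ic50 = float(10 ** rng.uniform(0, np.log10(500))) if route != 1 else float(
                10 ** rng.uniform(np.log10(501), np.log10(5e4))
            )
            rank = float(rng.uniform(0, 1)) if route != 0 else float(rng.uniform(2, 100))
        else:
            ic50 = float(10 ** rng.uniform(np.log10(501), np.log10(5e4)))
            rank = float(rng.uniform(1.5, 100))

        protein_pos = cds_idx // 3 + 1
        truth_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "transcript": tid,
                "gene": gene,
                "protein_pos": protein_pos,
                "wt_aa": wt_aa,
                "mut_aa": mut_aa,
                "peptide_id": f"{gene}_{wt_aa}{protein_pos}{mut_aa}",
                "maf_pct": round(maf, 4),
                "rna_mut_reads": mut_reads,
                "rna_wt_reads": wt_reads,
                "ic50_nM": round(ic50, 4),
                "mhc2_rank": round(rank, 4),
                "mhc_pass": mhc_pass,
                "maf_pass": maf_pass,
                "rna_pass": rna_pass,
                "pass_all": pass_all,
            }
        )
    truth = pd.DataFrame(truth_rows).sort_values("pos", ignore_index=True)

    # --- caller membership: Bernoulli subsets with guaranteed union coverage
    in_a = rng.random(len(truth)) < config.caller_sensitivity[0]
    in_b = rng.random(len(truth)) < config.caller_sensitivity[1]
    in_a |= ~(in_a | in_b)
    truth["in_" + config.caller_labels[0]] = in_a
    truth["in_" + config.caller_labels[1]] = in_b

    # --- write files -------------------------------------------------------
    genome_fasta = outdir / "genome.fasta"
    _write_fasta(genome_fasta, chrom, genome)
    gff3 = outdir / "transcripts.gff3"
    _write_gff3(gff3, chrom, transcripts)
    vcf_a = outdir / f"{config.caller_labels[0]}.vcf"
    vcf_b = outdir / f"{config.caller_labels[1]}.vcf"
    _write_vcf(vcf_a, chrom, len(genome), truth[in_a], config.caller_labels[0])
    _write_vcf(vcf_b, chrom, len(genome), truth[in_b], config.caller_labels[1])
    rna_tsv = outdir / "rna_counts.tsv"
    truth.rename(
        columns={"rna_mut_reads": "mut_reads", "rna_wt_reads": "wt_reads"}
    )[["chrom", "pos", "ref", "alt", "mut_reads", "wt_reads"]].to_csv(
        rna_tsv, sep="\t", index=False
    )
    binding_tsv = outdir / "binding.tsv"
    binding = truth[["peptide_id", "ic50_nM", "mhc2_rank"]].copy()
    binding["variant"] = (
        truth["chrom"] + ":" + truth["pos"].astype(str) + ":" + truth["ref"] + ">" + truth["alt"]
    )
    binding.to_csv(binding_tsv, sep="\t", index=False)
    truth_tsv = outdir / "truth.tsv"
    truth.to_csv(truth_tsv, sep="\t", index=False)

    return MutanomeBundle(
        genome_fasta=genome_fasta,
        transcripts_gff3=gff3,
        vcf_a=vcf_a,
        vcf_b=vcf_b,
        rna_counts_tsv=rna_tsv,
        binding_tsv=binding_tsv,
        truth_tsv=truth_tsv,
    )


def _cds_index_to_genomic(blocks, strand, cds_idx, cds_ref, cds_alt):
    """Map a 0-based CDS index (and its CDS-strand alleles) to plus-strand
    genomic (pos, ref, alt)."""
    total = sum(e - s + 1 for s, e in blocks)
    if strand == "+":
        plus_offset = cds_idx
        ref, alt = cds_ref, cds_alt
    else:
        plus_offset = total - 1 - cds_idx
        ref = cds_ref.translate(_COMPLEMENT)
        alt = cds_alt.translate(_COMPLEMENT)
    acc = 0
    for s, e in blocks:
        size = e - s + 1
        if plus_offset < acc + size:
            return s + (plus_offset - acc), ref, alt
        acc += size
    raise IndexError("CDS index outside blocks")


def _write_fasta(path: Path, name: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def _write_gff3(path: Path, chrom: str, transcripts) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tid, gene, strand, blocks, _ in transcripts:
            start = min(s for s, _ in blocks)
            end = max(e for _, e in blocks)
            fh.write(
                f"{chrom}\tneovax\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={tid};gene_name={gene}\n"
            )
            for j, (s, e) in enumerate(blocks):
                phase = 0 if j == 0 else (3 - (sum(bE - bS + 1 for bS, bE in blocks[:j]) % 3)) % 3
                fh.write(
                    f"{chrom}\tneovax\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}\t"
                    f"ID=cds-{tid}-{j};Parent={tid};gene_name={gene}\n"
                )


def _write_vcf(path: Path, chrom: str, contig_len: int, rows: pd.DataFrame, caller: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={caller}\n")
        fh.write(f"##contig=<ID={chrom},length={contig_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Tumor allele fraction">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n")
        for r in rows.sort_values("pos").itertuples():
            af = r.maf_pct / 100.0
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                f"GT:AF\t0/1:{af:.6f}\n"
            )


# ---------------------------------------------------------------------------
# Repertoire, ELISpot, DE tables
# ---------------------------------------------------------------------------


def simulate_repertoire(
    n_clonotypes: int,
    zipf_s: float,
    depth: int,
    seed: int,
    sample: str = "sim",
) -> pd.DataFrame:
    """MiXCR-export-shaped clonotype table with Zipf(s) abundance weights.

    Clone weights are proportional to 1/rank^s (s = 0 gives a perfectly even
    repertoire); reads are one guaranteed read per clonotype plus a
    multinomial draw of the remaining depth, so every clonotype is observed.
    """
    if n_clonotypes < 1:
        raise ValueError("n_clonotypes must be >= 1")
    if depth < n_clonotypes:
        raise ValueError(f"depth {depth} < n_clonotypes {n_clonotypes}")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_SUBSTREAMS["repertoire"],))
    )
    ranks = np.arange(1, n_clonotypes + 1, dtype=float)
    weights = ranks**-zipf_s
    weights /= weights.sum()
    counts = np.ones(n_clonotypes, dtype=int)
    counts += rng.multinomial(depth - n_clonotypes, weights)

    cdr3s = set()
    codons = [c for c in _NONSTOP_CODONS]
    rows = []
    for i in range(n_clonotypes):
        while True:
            n_codons = int(rng.integers(10, 16))
            nt = "TGT" + "".join(rng.choice(codons, size=n_codons - 2)) + "TTT"
            if nt not in cdr3s:
                cdr3s.add(nt)
                break
        v = int(rng.integers(1, 31))
        rows.append(
            {
                "cloneCount": int(counts[i]),
                "nSeqCDR3": nt,
                "aaSeqCDR3": str(Seq(nt).translate()),
                "allVHitsWithScore": f"TRBV{v}-1*00({int(rng.integers(500, 2000))})",
            }
        )
    return pd.DataFrame(rows)


def simulate_elispot(
    n_antigens: int,
    true_positive: Sequence,
    seed: int,
    background_sfc: float = 5.0,
    positive_sfc: float = 300.0,
    cona_sfc: float = 1500.0,
    densities: tuple = (400_000, 200_000),
    replicates: int = 2,
    mouse: str = "m1",
) -> pd.DataFrame:
    """Per-well ELISpot plate with planted positive antigens.

    Spot counts are Poisson with mean = rate x cells/10^6; planted positives
    get an antigen rate (default 300 SFC/10^6) that satisfies all three call
    conditions in expectation, everything else sits at background.  Wells are
    emitted in duplicate at two plating densities, like the assay layout.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_SUBSTREAMS["elispot"],))
    )
    positives = {str(a) for a in true_positive}
    antigens = [f"nAg{i + 1}" for i in range(n_antigens)]
    unknown = positives - set(antigens)
    if unknown:
        raise ValueError(f"planted positives not among antigens: {sorted(unknown)}")
    rows = []
    conditions = antigens + [
        "DMSO",
        "ConA",
    ]
    for antigen in conditions:
        if antigen == "DMSO":
            rate = background_sfc
        elif antigen == "ConA":
            rate = cona_sfc
        elif antigen in positives:
            rate = background_sfc + positive_sfc
        else:
            rate = background_sfc
        for density in densities:
            for rep in range(1, replicates + 1):
                lam = rate * density / 1e6
                rows.append(
                    {
                        "mouse": mouse,
                        "antigen": antigen,
                        "density": density,
                        "replicate": rep,
                        "spots": int(rng.poisson(lam)),
                        "cells_per_well": density,
                    }
                )
    return pd.DataFrame(rows)


def simulate_de_tables(
    n_genes: int,
    n_true: int,
    effect: float = 2.0,
    seed: int = 0,
    methods: tuple = ("deseq2", "edger", "limma_voom", "noiseq"),
) -> tuple:
    """Four per-method DE tables with planted true positives.

    True DEGs carry a shared signed effect around +/- ``effect`` log2 units,
    estimated by every method with small noise, and are given small p-values
    in at least 3 of the 4 methods (the 4th flags independently with
    probability 0.7).  Null genes get Uniform(0,1) p-values and
    Normal(0, 0.2) fold-change noise.

    Returns ``({method: DataFrame(gene, log2fc, pvalue)}, truth_gene_list)``.
    """
    if n_true > n_genes:
        raise ValueError("n_true cannot exceed n_genes")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_SUBSTREAMS["de"],))
    )
    genes = [f"g{i:05d}" for i in range(n_genes)]
    true_idx = rng.choice(n_genes, size=n_true, replace=False)
    is_true = np.zeros(n_genes, dtype=bool)
    is_true[true_idx] = True
    sign = rng.choice([-1.0, 1.0], size=n_genes)
    true_lfc = sign * rng.normal(effect, 0.15, size=n_genes)

    tables = {}
    flag = {}
    for m_i, method in enumerate(methods):
        flag[method] = np.zeros(n_genes, dtype=bool)
    # guarantee >= 3 flagging methods per true gene
    for g in np.flatnonzero(is_true):
        forced = rng.choice(len(methods), size=3, replace=False)
        for m_i in range(len(methods)):
            flag[methods[m_i]][g] = m_i in forced or rng.random() < 0.7

    for method in methods:
        lfc = np.where(is_true, true_lfc, 0.0) + rng.normal(0.0, 0.2, size=n_genes)
        p = rng.uniform(0.0, 1.0, size=n_genes)
        hot = flag[method] & is_true
        p[hot] = 10.0 ** rng.uniform(-8, -4, size=hot.sum())
        tables[method] = pd.DataFrame({"gene": genes, "log2fc": lfc, "pvalue": p})
    truth_genes = [genes[i] for i in sorted(true_idx)]
    return tables, truth_genes


def write_de_tables(tables: dict, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for method, df in tables.items():
        path = outdir / f"de_{method}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[method] = path
    return paths
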