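"""Somatic SNV ingestion, two-caller union-merge, and coding-effect annotation.

Somatic single-nucleotide variants are read from each caller's VCF, merged on
their genomic key (chrom, pos, ref, alt), and annotated at codon level against
transcript models to retain missense changes.  Tumor variant-allele fraction
(``maf``, in percent) and per-SNV RNA mutant/wild-type read counts are the
quantities the downstream selection funnel filters on; RNA counts are attached
from a locus-keyed TSV rather than recomputed from reads.

Coordinate conventions: VCF positions and reported loci are 1-based; interval
arithmetic inside this module is 0-based half-open; protein positions are
1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class ReferenceMismatchError(ValueError):
    """Genome base at a variant locus does not match the VCF REF allele."""


@dataclass(frozen=True)
class SomaticSNV:
    """One union-merged tumor SNV with caller provenance.

    ``maf`` is the tumor variant-allele fraction in percent (0-100).  RNA
    mutant/wild-type read counts are ``None`` until attached from the RNA
    counts table.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf: float
    callers: frozenset = field(default_factory=frozenset)
    rna_mut_reads: Optional[int] = None
    rna_wt_reads: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases in ACGT: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if not self.callers:
            raise ValueError(f"callers must be non-empty at {self.chrom}:{self.pos}")
        if not 0.0 <= self.maf <= 100.0:
            raise ValueError(f"maf out of [0, 100] at {self.chrom}:{self.pos}: {self.maf}")
        for name in ("rna_mut_reads", "rna_wt_reads"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} negative at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def locus(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class TranscriptModel:
    """A coding transcript as an ordered list of genomic CDS blocks.

    ``cds_blocks`` are 1-based inclusive genomic intervals, sorted by genomic
    position and non-overlapping; their concatenation (reverse-complemented on
    the minus strand) is the CDS, whose length must be a multiple of 3.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    cds_blocks: tuple

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -: {self.strand!r}")
        if not self.cds_blocks:
            raise ValueError(f"{self.transcript_id}: no CDS blocks")
        prev_end = 0
        for start, end in self.cds_blocks:
            if start > end:
                raise ValueError(f"{self.transcript_id}: block {start}-{end} inverted")
            if start <= prev_end:
                raise ValueError(f"{self.transcript_id}: blocks overlap or unsorted")
            prev_end = end
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_blocks)

    def cds_offset(self, pos: int) -> Optional[int]:
        """0-based offset of genomic position ``pos`` along the plus-strand CDS
        concatenation, or ``None`` if the position is outside every block."""
        offset = 0
        for start, end in self.cds_blocks:
            if start <= pos <= end:
                return offset + (pos - start)
            offset += end - start + 1
        return None

    def cds_sequence(self, genome: Mapping) -> str:
        parts = [_fetch(genome, self.chrom, s - 1, e) for s, e in self.cds_blocks]
        cds = "".join(parts)
        if self.strand == "-":
            cds = cds.translate(_COMPLEMENT)[::-1]
        return cds

    def protein_sequence(self, genome: Mapping) -> str:
        """Translated CDS with the trailing stop (if any) removed."""
        aa = str(Seq(self.cds_sequence(genome)).translate())
        return aa[:-1] if aa.endswith("*") else aa


@dataclass(frozen=True)
class CodingEffect:
    """Codon-level consequence of an SNV on one transcript."""

    snv: SomaticSNV
    transcript_id: str
    gene_symbol: str
    protein_pos: int  # 1-based
    wt_aa: str
    mut_aa: str
    effect_class: str  # missense | synonymous | nonsense | stoploss

    def __post_init__(self) -> None:
        if self.effect_class == "missense":
            ok = (
                self.wt_aa != self.mut_aa
                and self.wt_aa in STANDARD_AA
                and self.mut_aa in STANDARD_AA
            )
            if not ok:
                raise ValueError(
                    f"missense requires two distinct standard residues, got "
                    f"{self.wt_aa}>{self.mut_aa}"
                )


def _fetch(genome: Mapping, chrom: str, start0: int, end0: int) -> str:
    """Slice [start0, end0) from a genome store (dict of str or pyfaidx.Fasta)."""
    return str(genome[chrom][start0:end0]).upper()


# ---------------------------------------------------------------------------
# VCF reading and merging
# ---------------------------------------------------------------------------


def read_snv_calls(
    path,
    caller_label: str,
    af_key: str = "AF",
    sample: Optional[str] = None,
) -> list:
    """Read biallelic SNVs from one caller's VCF.

    Multi-allelic records are split into biallelic SNVs; records whose REF or
    ALT is not a single A/C/G/T base are skipped and the skip count is logged.
    The tumor allele fraction is read from FORMAT ``af_key`` of the chosen
    sample (default: first sample) and falls back to INFO ``af_key``; a record
    carrying neither raises with the record locus.
    """
    vf = pysam.VariantFile(str(path))
    sample_name = sample
    if sample_name is None and list(vf.header.samples):
        sample_name = list(vf.header.samples)[0]

    out: dict = {}
    skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        for i, alt in enumerate(alts):
            ref = (rec.ref or "").upper()
            alt = (alt or "").upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                skipped += 1
                continue
            af = _allele_fraction(rec, i, af_key, sample_name)
            snv = SomaticSNV(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=ref,
                alt=alt,
                # FORMAT floats come back as float32; round away the artifact
                maf=round(af * 100.0, 4),
                callers=frozenset({caller_label}),
            )
            if snv.key in out:
                # same locus listed twice within one caller: keep the higher MAF
                if snv.maf > out[snv.key].maf:
                    out[snv.key] = snv
                log.warning("duplicate record for %s in %s", snv.locus, path)
            else:
                out[snv.key] = snv
    if skipped:
        log.info("read_snv_calls(%s): skipped %d non-SNV allele(s)", path, skipped)
    return sorted(out.values(), key=lambda s: s.key)


def _allele_fraction(rec, alt_index: int, af_key: str, sample_name: Optional[str]) -> float:
    locus = f"{rec.chrom}:{rec.pos}"
    value = None
    if sample_name is not None:
        try:
            value = rec.samples[sample_name].get(af_key)
        except KeyError:
            value = None
    if value is None:
        value = rec.info.get(af_key) if af_key in rec.info else None
    if value is None:
        raise ValueError(f"missing allele-fraction field {af_key!r} at {locus}")
    if isinstance(value, (tuple, list)):
        value = value[alt_index] if alt_index < len(value) else value[0]
    try:
        af = float(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"unparsable allele fraction {value!r} at {locus}") from exc
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele fraction {af} out of [0, 1] at {locus}")
    return af


def union_merge(calls_a: Sequence, calls_b: Sequence) -> list:
    """Union of two callers' SNV lists on (chrom, pos, ref, alt).

    Shared variants carry the union of caller labels; the merged MAF is the
    maximum of the two callers' values (the funnel threshold is a >=, so the
    maximum is the permissive, reproducible reconciliation).  Conflicting
    non-missing RNA read counts raise, naming the locus.
    """
    merged: dict = {}
    for snv in list(calls_a) + list(calls_b):
        prev = merged.get(snv.key)
        if prev is None:
            merged[snv.key] = snv
            continue
        mut, wt = _merge_counts(prev, snv)
        merged[snv.key] = replace(
            prev,
            maf=max(prev.maf, snv.maf),
            callers=prev.callers | snv.callers,
            rna_mut_reads=mut,
            rna_wt_reads=wt,
        )
    return sorted(merged.values(), key=lambda s: s.key)


def _merge_counts(a: SomaticSNV, b: SomaticSNV) -> tuple:
    pairs = []
    for name in ("rna_mut_reads", "rna_wt_reads"):
        va, vb = getattr(a, name), getattr(b, name)
        if va is not None and vb is not None and va != vb:
            raise ValueError(f"conflicting {name} at {a.locus}: {va} vs {vb}")
        pairs.append(va if va is not None else vb)
    return tuple(pairs)


def read_rna_counts(path) -> dict:
    """RNA counts TSV (`chrom pos ref alt mut_reads wt_reads`) -> locus-keyed dict."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "mut_reads", "wt_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"RNA counts table missing columns: {sorted(missing)}")
    return {
        (r.chrom, int(r.pos), r.ref, r.alt): (int(r.mut_reads), int(r.wt_reads))
        for r in df.itertuples()
    }


def attach_rna_counts(snvs: Sequence, counts: Mapping) -> list:
    """Attach locus-keyed (mut, wt) RNA read counts; missing loci get (0, 0)."""
    out = []
    for snv in snvs:
        if snv.key in counts:
            mut, wt = counts[snv.key]
        else:
            log.warning("no RNA counts for %s; assuming 0/0", snv.locus)
            mut, wt = 0, 0
        out.append(replace(snv, rna_mut_reads=mut, rna_wt_reads=wt))
    return out


# ---------------------------------------------------------------------------
# Transcript models and coding effects
# ---------------------------------------------------------------------------


def read_transcripts_gff3(path) -> list:
    """Read transcript models from GFF3 CDS features.

    CDS features are grouped by their ``Parent`` attribute; ``gene_name``
    supplies the gene symbol (falls back to the transcript id).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        force=True,
    )
    grouped: dict = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent", [feat.id])
        for parent in parents:
            info = grouped.setdefault(
                parent,
                {
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "gene": feat.attributes.get("gene_name", [parent])[0],
                    "blocks": [],
                },
            )
            info["blocks"].append((feat.start, feat.end))
    models = []
    for tid, info in grouped.items():
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_symbol=info["gene"],
                chrom=info["chrom"],
                strand=info["strand"],
                cds_blocks=tuple(sorted(info["blocks"])),
            )
        )
    return sorted(models, key=lambda m: m.transcript_id)


def annotate_coding(
    snv: SomaticSNV, model: TranscriptModel, genome: Mapping
) -> Optional[CodingEffect]:
    """Codon-level effect of ``snv`` on ``model``, or ``None`` outside its CDS.

    The genome reference base at the locus must equal the VCF REF allele
    (both on plus-strand coordinates), otherwise :class:`ReferenceMismatchError`
    is raised.
    """
    if snv.chrom != model.chrom:
        return None
    offset = model.cds_offset(snv.pos)
    if offset is None:
        return None
    genome_base = _fetch(genome, snv.chrom, snv.pos - 1, snv.pos)
    if genome_base != snv.ref:
        raise ReferenceMismatchError(
            f"genome has {genome_base} but VCF REF is {snv.ref} at {snv.locus}"
        )
    cds = model.cds_sequence(genome)
    if model.strand == "+":
        idx = offset
        ref_c, alt_c = snv.ref, snv.alt
    else:
        idx = len(cds) - 1 - offset
        ref_c = snv.ref.translate(_COMPLEMENT)
        alt_c = snv.alt.translate(_COMPLEMENT)
    if cds[idx] != ref_c:
        raise ReferenceMismatchError(
            f"CDS base {cds[idx]} != expected {ref_c} at {snv.locus} "
            f"({model.transcript_id})"
        )
    codon_i = idx // 3
    wt_codon = cds[codon_i * 3 : codon_i * 3 + 3]
    within = idx % 3
    mut_codon = wt_codon[:within] + alt_c + wt_codon[within + 1 :]
    wt_aa = str(Seq(wt_codon).translate())
    mut_aa = str(Seq(mut_codon).translate())
    if wt_aa == mut_aa:
        effect = "synonymous"
    elif mut_aa == "*":
        effect = "nonsense"
    elif wt_aa == "*":
        effect = "stoploss"
    else:
        effect = "missense"
    return CodingEffect(
        snv=snv,
        transcript_id=model.transcript_id,
        gene_symbol=model.gene_symbol,
        protein_pos=codon_i + 1,
        wt_aa=wt_aa,
        mut_aa=mut_aa,
        effect_class=effect,
    )


def annotate_all(
    snvs: Sequence, models: Sequence, genome: Mapping, effect_class: Optional[str] = "missense"
) -> list:
    """Annotate every SNV against every transcript containing its position.

    Returns one :class:`CodingEffect` per (SNV, containing transcript),
    optionally restricted to one ``effect_class`` (default missense, the
    class the neoantigen pipeline consumes).
    """
    by_chrom: dict = {}
    for model in models:
        by_chrom.setdefault(model.chrom, []).append(model)
    effects = []
    for snv in snvs:
        for model in by_chrom.get(snv.chrom, []):
            eff = annotate_coding(snv, model, genome)
            if eff is not None and (effect_class is None or eff.effect_class == effect_class):
                effects.append(eff)
    return effects


def collapse_by_gene(effects: Sequence, models: Sequence) -> list:
    """Keep one effect per (SNV, gene), preferring the longest CDS.

    Overlapping transcripts of a gene may each yield an effect for the same
    SNV; downstream peptide design needs a single deterministic choice.  Ties
    on CDS length break on transcript id.
    """
    length = {m.transcript_id: m.cds_length for m in models}
    best: dict = {}
    for eff in effects:
        k = (eff.snv.key, eff.gene_symbol)
        rank = (-length.get(eff.transcript_id, 0), eff.transcript_id)
        if k not in best or rank < best[k][0]:
            best[k] = (rank, eff)
    return [eff for _, eff in sorted(best.values(), key=lambda t: (t[1].snv.key, t[1].gene_symbol))]


def annotated_table(effects: Sequence) -> pd.DataFrame:
    """Merged/annotated SNVs as the documented flat TSV layout."""
    rows = []
    for eff in effects:
        s = eff.snv
        rows.append(
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref,
                "alt": s.alt,
                "maf": s.maf,
                "callers": ",".join(sorted(s.callers)),
                "mut_reads": s.rna_mut_reads,
                "wt_reads": s.rna_wt_reads,
                "gene": eff.gene_symbol,
                "transcript": eff.transcript_id,
                "protein_pos": eff.protein_pos,
                "wt_aa": eff.wt_aa,
                "mut_aa": eff.mut_aa,
                "effect": eff.effect_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "maf", "callers", "mut_reads", "wt_reads",
            "gene", "transcript", "protein_pos", "wt_aa", "mut_aa", "effect",
        ],
    )
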