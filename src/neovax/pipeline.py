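"""End-to-end selection driver: VCFs -> merged missense SNVs -> peptides ->
binding scores -> funnel verdicts.

This is the glue the CLI ``select`` subcommand and the synthetic-data
round-trip tests share; each step lives in (and is documented by) its own
module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import pyfaidx

from . import funnel as funnel_mod
from . import peptides as peptides_mod
from . import variants as variants_mod
from .funnel import CandidateRecord, FunnelConfig


@dataclass
class SelectionResult:
    candidates: list  # CandidateRecord, funnel applied, input order
    report: pd.DataFrame
    effects: list  # CodingEffect, one per (SNV, gene)

    @property
    def selected(self):
        return funnel_mod.selected(self.candidates)


def load_genome(path) -> Mapping:
    return pyfaidx.Fasta(str(path))


def select_neoantigens(
    vcf_a,
    vcf_b,
    gff3,
    genome_fasta,
    rna_counts_tsv,
    predictor,
    config: FunnelConfig = FunnelConfig(),
    caller_labels: Sequence = ("callerA", "callerB"),
    af_key: str = "AF",
    window: int = 12,
) -> SelectionResult:
    """Run the full neoantigen selection pipeline on file inputs.

    ``predictor`` is any binding predictor (a
    :class:`~neovax.funnel.TableBindingPredictor` over precomputed scores, or
    the seeded mock).  Candidates are ordered by genomic locus; peptides that
    share a locus on several genes each yield a candidate.
    """
    calls_a = variants_mod.read_snv_calls(vcf_a, caller_labels[0], af_key=af_key)
    calls_b = variants_mod.read_snv_calls(vcf_b, caller_labels[1], af_key=af_key)
    merged = variants_mod.union_merge(calls_a, calls_b)
    merged = variants_mod.attach_rna_counts(
        merged, variants_mod.read_rna_counts(rna_counts_tsv)
    )

    models = variants_mod.read_transcripts_gff3(gff3)
    genome = load_genome(genome_fasta)
    effects = variants_mod.annotate_all(merged, models, genome, effect_class="missense")
    effects = variants_mod.collapse_by_gene(effects, models)

    proteins = {
        m.transcript_id: m.protein_sequence(genome)
        for m in models
        if any(e.transcript_id == m.transcript_id for e in effects)
    }

    by_transcript: dict = {}
    for eff in effects:
        by_transcript.setdefault(eff.transcript_id, []).append(eff)

    candidates = []
    for tid in sorted(by_transcript):
        effs = by_transcript[tid]
        for group in peptides_mod.group_nearby(effs, window=window):
            peptide = peptides_mod.design_peptide(proteins[tid], group, flank=window)
            scores = funnel_mod.predict_binding(peptide, predictor)
            # a multi-mutation peptide inherits the SNV of its first mutation
            candidates.append(
                CandidateRecord(peptide=peptide, snv=group[0].snv, scores=scores)
            )
    candidates.sort(key=lambda c: c.snv.key)
    candidates = funnel_mod.apply_funnel(candidates, config)
    return SelectionResult(
        candidates=candidates,
        report=funnel_mod.funnel_report(candidates),
        effects=effects,
    )
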