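"""Packaged fixtures: published neoantigen tables and the mouse codon-usage table.

The CT26 table holds the 31 neoantigens encoded by the 31-segment vaccine with
their RNA mutant/wild-type read counts, tumor MAF, MHC-I IC50 and MHC-II rank;
the MC38 table holds the 7 mass-spectrometry-derived neoantigens of the
7-segment vaccine.  Bracket notation is mutant-first ([mut/wt]) in both files.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .constructs import read_codon_usage
from .funnel import BindingScores, CandidateRecord
from .peptides import NeoantigenPeptide, parse_bracket
from .variants import SomaticSNV


def _data_path(name: str):
    return resources.files("neovax").joinpath("data", name)


@lru_cache(maxsize=None)
def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def ct26_neoantigens() -> pd.DataFrame:
    """The 31-record CT26 neoantigen table (copy; safe to mutate)."""
    return _read_tsv("ct26_neoantigens.tsv").copy()


def mc38_neoantigens() -> pd.DataFrame:
    """The 7-record MC38 neoantigen table (copy; safe to mutate)."""
    return _read_tsv("mc38_neoantigens.tsv").copy()


@lru_cache(maxsize=None)
def mouse_codon_usage() -> dict:
    with resources.as_file(_data_path("mouse_codon_usage.tsv")) as path:
        return read_codon_usage(path)


def _peptide_from_row(row) -> NeoantigenPeptide:
    parsed = parse_bracket(row.sequence)
    return NeoantigenPeptide(
        gene_symbol=row.gene,
        sequence=parsed.sequence,
        mutation_offsets=parsed.mutation_offsets,
        wt_residues=parsed.wt_residues,
        # source-protein coordinates are not printed; in-peptide offsets stand in
        protein_positions=parsed.mutation_offsets,
        upstream_flank_len=parsed.upstream_flank_len,
        downstream_flank_len=parsed.downstream_flank_len,
    )


def ct26_candidates() -> list:
    """The CT26 table as funnel-ready candidate records.

    Genomic coordinates are not printed in the source table, so each record
    carries a synthetic placeholder locus; MAF, RNA read counts, and binding
    scores are the transcribed values the funnel actually consumes.
    """
    out = []
    for row in ct26_neoantigens().itertuples():
        peptide = _peptide_from_row(row)
        snv = SomaticSNV(
            chrom="fixture",
            pos=int(row.id),
            ref="A",
            alt="C",
            maf=float(row.maf_pct),
            callers=frozenset({"published"}),
            rna_mut_reads=int(row.rna_mut),
            rna_wt_reads=int(row.rna_wt),
        )
        scores = BindingScores(
            mhc1_ic50=float(row.mhc1_ic50), mhc2_rank=float(row.mhc2_score)
        )
        out.append(CandidateRecord(peptide=peptide, snv=snv, scores=scores))
    return out


def mc38_segments() -> list:
    """MC38 peptides as (id, mutant sequence) pairs for construct assembly."""
    out = []
    for row in mc38_neoantigens().itertuples():
        parsed = parse_bracket(row.sequence)
        out.append((f"{row.gene}_{row.id}", parsed.sequence))
    return out
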