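"""Polyepitope construct assembly and codon-usage back-translation.

Selected neoantigen peptides are joined head to tail, in the order given and
with no linkers, into one artificial protein; the corresponding gene is
obtained by back-translating with the most-frequent codon per residue from a
codon-usage table (packaged mouse table by default).  Junction bookkeeping and
a GFF3 feature per segment let each peptide be traced back to its coordinates
in the construct.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variants import STANDARD_AA


@dataclass(frozen=True)
class PolyepitopeConstruct:
    name: str
    peptide_ids: tuple
    protein_sequence: str
    junctions: tuple  # 1-based protein position where segment i ends
    dna_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.junctions) != len(self.peptide_ids) - 1:
            raise ValueError("junction count must equal number of peptides - 1")
        if self.dna_sequence is not None:
            if len(self.dna_sequence) != 3 * len(self.protein_sequence):
                raise ValueError("dna length must be 3x protein length")
            if str(Seq(self.dna_sequence).translate()) != self.protein_sequence:
                raise ValueError("dna does not translate to the protein sequence")

    @property
    def n_segments(self) -> int:
        return len(self.peptide_ids)

    def segment_bounds(self) -> list:
        """(start, end) 1-based inclusive protein coordinates per segment."""
        bounds = []
        start = 1
        for end in list(self.junctions) + [len(self.protein_sequence)]:
            bounds.append((start, end))
            start = end + 1
        return bounds

    def segment_sequence(self, i: int) -> str:
        start, end = self.segment_bounds()[i]
        return self.protein_sequence[start - 1 : end]


def _id_and_sequence(item) -> Tuple[str, str]:
    if isinstance(item, tuple):
        return item
    if isinstance(item, str):
        return item, item
    return item.id, item.sequence


def assemble(peptides: Sequence, name: str = "construct") -> PolyepitopeConstruct:
    """Join peptides head to tail into one artificial protein.

    Accepts :class:`~neovax.peptides.NeoantigenPeptide` objects, plain
    sequences, or (id, sequence) pairs.  Order is the contract: permuting the
    input permutes the segments identically, nothing is reordered or linked.
    """
    items = [_id_and_sequence(p) for p in peptides]
    if not items:
        raise ValueError("cannot assemble an empty peptide list")
    protein = "".join(seq for _, seq in items)
    junctions = []
    acc = 0
    for _, seq in items[:-1]:
        acc += len(seq)
        junctions.append(acc)
    return PolyepitopeConstruct(
        name=name,
        peptide_ids=tuple(pid for pid, _ in items),
        protein_sequence=protein,
        junctions=tuple(junctions),
    )


def read_codon_usage(path) -> dict:
    """Codon-usage TSV (`codon amino_acid per_1000`) -> {codon: (aa, freq)}."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return {r.codon: (r.amino_acid, float(r.per_1000)) for r in df.itertuples()}


def preferred_codons(usage: Mapping) -> dict:
    """Most-frequent codon per residue; frequency ties break on the
    lexicographically smallest codon for determinism."""
    best: dict = {}
    for codon in sorted(usage):
        aa, freq = usage[codon]
        if aa not in best or freq > best[aa][1]:
            best[aa] = (codon, freq)
    return {aa: codon for aa, (codon, _) in best.items()}


def back_translate(protein: str, usage: Optional[Mapping] = None) -> str:
    """Deterministic reverse translation using the preferred codon per residue.

    ``usage`` defaults to the packaged mouse codon-usage table.  The round
    trip ``translate(back_translate(p)) == p`` holds for any protein over the
    20 standard amino acids; a non-standard residue raises, naming its
    position.
    """
    if usage is None:
        from .datasets import mouse_codon_usage

        usage = mouse_codon_usage()
    table = preferred_codons(usage)
    codons = []
    for i, aa in enumerate(protein, start=1):
        if aa not in STANDARD_AA:
            raise ValueError(f"non-standard residue {aa!r} at position {i}")
        codons.append(table[aa])
    return "".join(codons)


def with_dna(construct: PolyepitopeConstruct, usage: Optional[Mapping] = None) -> PolyepitopeConstruct:
    dna = back_translate(construct.protein_sequence, usage)
    return PolyepitopeConstruct(
        name=construct.name,
        peptide_ids=construct.peptide_ids,
        protein_sequence=construct.protein_sequence,
        junctions=construct.junctions,
        dna_sequence=dna,
    )


def write_construct(construct: PolyepitopeConstruct, outdir) -> dict:
    """Write protein FASTA, DNA FASTA (if present), and a GFF3 feature table.

    The GFF3 carries one feature per segment on the protein coordinate system
    (1-based inclusive, abutting intervals); feature attributes record the
    peptide id and segment index.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    prot_path = outdir / f"{construct.name}_protein.fasta"
    SeqIO.write(
        [SeqRecord(Seq(construct.protein_sequence), id=construct.name, description="polyepitope protein")],
        prot_path,
        "fasta",
    )
    paths["protein_fasta"] = prot_path

    if construct.dna_sequence is not None:
        dna_path = outdir / f"{construct.name}_dna.fasta"
        SeqIO.write(
            [SeqRecord(Seq(construct.dna_sequence), id=construct.name, description="polyepitope CDS")],
            dna_path,
            "fasta",
        )
        paths["dna_fasta"] = dna_path

    gff_path = outdir / f"{construct.name}_segments.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (start, end) in enumerate(construct.segment_bounds()):
            attrs = f"ID=segment{i + 1};peptide_id={construct.peptide_ids[i]}"
            fh.write(
                "\t".join(
                    [construct.name, "neovax", "polypeptide_region",
                     str(start), str(end), ".", "+", ".", attrs]
                )
                + "\n"
            )
    paths["segments_gff3"] = gff_path
    return paths
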