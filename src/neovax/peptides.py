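"""Neoantigen peptide design: 25-mer windows around missense mutations.

Each amino-acid change is flanked upstream and downstream by 12 wild-type
residues for a total length of 25, maximizing the number of potential CD4/CD8
epitopes the peptide can carry.  Windows are clipped (never padded) at the
protein termini.  Mutations closer than the flank width on the same protein
are merged into a single peptide: the last mutation keeps its full 12-residue
downstream flank and the upstream flank absorbs whatever budget the 25-aa cap
leaves.

Peptides shorter than 8 residues after terminal clipping are flagged as too
short for MHC class I presentation but are kept; discarding is the funnel's
decision, not the designer's.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence

from .variants import STANDARD_AA, CodingEffect

MHC1_MIN_LENGTH = 8

_BRACKET_RE = re.compile(r"\[([A-Z*])/([A-Z*])\]")


@dataclass(frozen=True)
class NeoantigenPeptide:
    """A peptide window around one or more mutated residues.

    ``sequence`` is the mutant peptide; positions outside ``mutation_offsets``
    equal the wild-type protein.  ``wt_residues`` are the replaced residues
    aligned with ``mutation_offsets`` (both 1-based within the peptide);
    ``protein_positions`` are the 1-based source-protein coordinates of the
    mutations.
    """

    gene_symbol: str
    sequence: str
    mutation_offsets: tuple
    wt_residues: tuple
    protein_positions: tuple
    upstream_flank_len: int
    downstream_flank_len: int

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n < 1:
            raise ValueError("empty peptide")
        if not (
            len(self.mutation_offsets)
            == len(self.wt_residues)
            == len(self.protein_positions)
            > 0
        ):
            raise ValueError("mutation bookkeeping fields must align and be non-empty")
        for off, wt in zip(self.mutation_offsets, self.wt_residues):
            if not 1 <= off <= n:
                raise ValueError(f"mutation offset {off} outside peptide of length {n}")
            if self.sequence[off - 1] == wt:
                raise ValueError(f"residue at offset {off} equals wild-type {wt}")

    @property
    def too_short(self) -> bool:
        """True when the clipped peptide cannot be presented on MHC class I."""
        return len(self.sequence) < MHC1_MIN_LENGTH

    @property
    def id(self) -> str:
        changes = "_".join(
            f"{wt}{pos}{self.sequence[off - 1]}"
            for off, wt, pos in zip(
                self.mutation_offsets, self.wt_residues, self.protein_positions
            )
        )
        return f"{self.gene_symbol}_{changes}"

    @property
    def bracket(self) -> str:
        """Report notation with each mutated residue as ``[mut/wt]``."""
        out = []
        muts = dict(zip(self.mutation_offsets, self.wt_residues))
        for i, aa in enumerate(self.sequence, start=1):
            if i in muts:
                out.append(f"[{aa}/{muts[i]}]")
            else:
                out.append(aa)
        return "".join(out)

    def wild_type_sequence(self) -> str:
        seq = list(self.sequence)
        for off, wt in zip(self.mutation_offsets, self.wt_residues):
            seq[off - 1] = wt
        return "".join(seq)


def parse_bracket(notation: str) -> NeoantigenPeptide:
    """Parse ``[mut/wt]`` notation into a peptide record (gene unknown).

    Protein positions are unrecoverable from the notation alone and are set to
    the in-peptide offsets (i.e. as if the window started at residue 1).
    """
    sequence = []
    offsets: List[int] = []
    wts: List[str] = []
    i = 0
    pos = 0
    while i < len(notation):
        m = _BRACKET_RE.match(notation, i)
        if m:
            pos += 1
            sequence.append(m.group(1))
            offsets.append(pos)
            wts.append(m.group(2))
            i = m.end()
        else:
            ch = notation[i]
            if not (ch.isalpha() and ch.isupper()):
                raise ValueError(f"unexpected character {ch!r} in bracket notation")
            pos += 1
            sequence.append(ch)
            i += 1
    return NeoantigenPeptide(
        gene_symbol="",
        sequence="".join(sequence),
        mutation_offsets=tuple(offsets),
        wt_residues=tuple(wts),
        protein_positions=tuple(offsets),
        upstream_flank_len=offsets[0] - 1 if offsets else 0,
        downstream_flank_len=pos - offsets[-1] if offsets else 0,
    )


def group_nearby(mutations: Sequence, window: int = 12) -> list:
    """Partition same-transcript mutations into maximal groups of nearby sites.

    Mutations whose protein positions differ by at most ``window`` chain into
    one group (transitively); the result is the list of maximal chains, each
    sorted by protein position.
    """
    if not mutations:
        return []
    transcripts = {m.transcript_id for m in mutations}
    if len(transcripts) > 1:
        raise ValueError(f"mutations span multiple transcripts: {sorted(transcripts)}")
    ordered = sorted(mutations, key=lambda m: m.protein_pos)
    groups = [[ordered[0]]]
    for mut in ordered[1:]:
        if mut.protein_pos - groups[-1][-1].protein_pos <= window:
            groups[-1].append(mut)
        else:
            groups.append([mut])
    return groups


def design_peptide(
    protein: str,
    group: Sequence,
    max_len: int = 25,
    flank: int = 12,
) -> NeoantigenPeptide:
    """Design the peptide window covering one mutation group.

    A single internal mutation gets ``flank`` wild-type residues on both
    sides; flanks are truncated at the protein termini.  Multi-mutation groups
    keep the full downstream flank of the last mutation and give the upstream
    remainder (``max_len`` - span - ``flank``) to the first, reproducing the
    published double-mutation window geometry.
    """
    if not group:
        raise ValueError("empty mutation group")
    muts = sorted(group, key=lambda m: m.protein_pos)
    length = len(protein)
    for m in muts:
        if not 1 <= m.protein_pos <= length:
            raise ValueError(
                f"mutation position {m.protein_pos} outside protein of length {length}"
            )
        actual = protein[m.protein_pos - 1]
        if actual != m.wt_aa:
            raise ValueError(
                f"wild-type mismatch at position {m.protein_pos}: "
                f"protein has {actual}, expected {m.wt_aa}"
            )
    first, last = muts[0].protein_pos, muts[-1].protein_pos
    span = last - first + 1
    if span > max_len:
        raise ValueError(f"mutation group spans {span} residues, exceeds cap {max_len}")
    down = min(flank, max_len - span)
    up = max_len - span - down
    start = max(1, first - up)
    end = min(length, last + down)
    window = list(protein[start - 1 : end])
    offsets, wts, positions = [], [], []
    for m in muts:
        off = m.protein_pos - start + 1
        window[off - 1] = m.mut_aa
        offsets.append(off)
        wts.append(m.wt_aa)
        positions.append(m.protein_pos)
    return NeoantigenPeptide(
        gene_symbol=muts[0].gene_symbol,
        sequence="".join(window),
        mutation_offsets=tuple(offsets),
        wt_residues=tuple(wts),
        protein_positions=tuple(positions),
        upstream_flank_len=first - start,
        downstream_flank_len=end - last,
    )


def design_all(
    effects: Sequence,
    proteins: Mapping,
    window: int = 12,
    max_len: int = 25,
) -> list:
    """Group missense effects per transcript and design every peptide.

    ``proteins`` maps transcript id to the wild-type protein sequence.
    Output order follows (gene, first protein position) for determinism.
    """
    by_transcript: dict = {}
    for eff in effects:
        by_transcript.setdefault(eff.transcript_id, []).append(eff)
    out = []
    for tid in sorted(by_transcript):
        protein = proteins[tid]
        for grp in group_nearby(by_transcript[tid], window=window):
            out.append(design_peptide(protein, grp, max_len=max_len, flank=window))
    out.sort(key=lambda p: (p.gene_symbol, p.protein_positions[0]))
    return out
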