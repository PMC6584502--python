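"""Sequential neoantigen prioritization: MHC binding, tumor MAF, RNA expression.

Candidates pass the funnel when they satisfy, in order:

1. MHC binding — predicted class-I IC50 <= 500 nM **or** class-II percentile
   rank <= 1 (the published selected set contains candidates passing only one
   of the two classes, so the combination is an OR);
2. tumor variant-allele fraction >= 25%;
3. RNA expression — at least 1 mutated RNA read.

Boundaries are inclusive exactly as printed.  ``rejection_stage`` records the
first failing stage in funnel order, so relaxing any single threshold can only
grow the selected set.

Binding prediction is pluggable: a precomputed score table (the normal route —
external consensus predictors are not reimplemented here) or a seeded mock
predictor that derives reproducible pseudo-scores from peptide k-mer hashes.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Mapping, Optional, Protocol, Sequence

import pandas as pd
import yaml

from .peptides import NeoantigenPeptide
from .variants import SomaticSNV

log = logging.getLogger(__name__)

STAGES = ("mhc", "maf", "rna")


@dataclass(frozen=True)
class BindingScores:
    """Best-allele MHC-I IC50 (nM) and MHC-II percentile-style rank (lower = better)."""

    mhc1_ic50: float
    mhc2_rank: float

    def __post_init__(self) -> None:
        if self.mhc1_ic50 < 0 or self.mhc2_rank < 0:
            raise ValueError("binding scores must be non-negative")
        if self.mhc2_rank > 100:
            raise ValueError(f"mhc2_rank {self.mhc2_rank} exceeds 100")


@dataclass(frozen=True)
class FunnelConfig:
    ic50_max_nM: float = 500.0
    mhc2_rank_max: float = 1.0
    maf_min_pct: float = 25.0
    rna_mut_reads_min: int = 1

    def __post_init__(self) -> None:
        for name in ("ic50_max_nM", "mhc2_rank_max", "maf_min_pct", "rna_mut_reads_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "FunnelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(frozen=True)
class CandidateRecord:
    """A peptide with its source SNV, binding scores, and funnel verdict."""

    peptide: NeoantigenPeptide
    snv: SomaticSNV
    scores: Optional[BindingScores] = None
    verdict: str = "pending"  # pending until the funnel has run
    rejection_stage: Optional[str] = None

    def __post_init__(self) -> None:
        if self.verdict not in ("pending", "selected", "rejected"):
            raise ValueError(f"unknown verdict: {self.verdict}")
        if self.verdict in ("pending", "selected") and self.rejection_stage is not None:
            raise ValueError("rejection_stage only applies to rejected candidates")
        if self.verdict == "rejected" and self.rejection_stage is None:
            raise ValueError("rejected candidates must name the failing stage")
        if self.rejection_stage is not None and self.rejection_stage not in STAGES:
            raise ValueError(f"unknown rejection stage {self.rejection_stage}")


class BindingPredictor(Protocol):
    min_length: int

    def predict(self, peptide: NeoantigenPeptide) -> Optional[BindingScores]: ...


class MockBindingPredictor:
    """Deterministic pseudo-predictor for pipeline testing.

    Scores are derived from a seeded hash of the peptide's k-mer multiset:
    pseudo-IC50 log-uniform on [1, 5e4] nM and pseudo-rank uniform on [0, 100].
    The same peptide sequence always receives the same scores for a fixed
    seed; allele identity is deliberately ignored.
    """

    min_length = 8

    def __init__(self, seed: int = 0, k: int = 3):
        self.seed = seed
        self.k = k

    def _unit(self, sequence: str, tag: str) -> float:
        kmers = [sequence[i : i + self.k] for i in range(max(1, len(sequence) - self.k + 1))]
        acc = 0
        for kmer in kmers:
            digest = hashlib.sha256(f"{self.seed}:{tag}:{kmer}".encode()).digest()
            acc = (acc + int.from_bytes(digest[:8], "big")) % (1 << 53)
        return acc / float(1 << 53)

    def predict(self, peptide: NeoantigenPeptide) -> Optional[BindingScores]:
        seq = peptide.sequence
        if len(seq) < self.min_length:
            return None
        ic50 = 10.0 ** (self._unit(seq, "ic50") * math.log10(5e4))
        rank = self._unit(seq, "rank") * 100.0
        return BindingScores(mhc1_ic50=ic50, mhc2_rank=rank)


class TableBindingPredictor:
    """Look up precomputed scores by peptide id (falling back to sequence)."""

    min_length = 1

    def __init__(self, table: Mapping):
        self.table = dict(table)

    @classmethod
    def from_tsv(cls, path) -> "TableBindingPredictor":
        df = pd.read_csv(path, sep="\t")
        required = {"peptide_id", "ic50_nM", "mhc2_rank"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"binding table missing columns: {sorted(missing)}")
        return cls(
            {
                r.peptide_id: BindingScores(float(r.ic50_nM), float(r.mhc2_rank))
                for r in df.itertuples()
            }
        )

    def predict(self, peptide: NeoantigenPeptide) -> Optional[BindingScores]:
        if peptide.id in self.table:
            return self.table[peptide.id]
        return self.table.get(peptide.sequence)


def predict_binding(
    peptide: NeoantigenPeptide, predictor: BindingPredictor
) -> Optional[BindingScores]:
    """Score one peptide; ``None`` (a flagged missing score) below the
    predictor's minimum length or when a table predictor has no entry."""
    if len(peptide.sequence) < getattr(predictor, "min_length", 1):
        log.warning("peptide %s shorter than predictor minimum; missing scores", peptide.id)
        return None
    return predictor.predict(peptide)


def apply_funnel(candidates: Sequence, config: FunnelConfig = FunnelConfig()) -> list:
    """Evaluate the three-stage funnel on every candidate.

    Returns new records with ``verdict`` and ``rejection_stage`` set; input
    order is preserved (the published set is not re-ranked internally).
    Missing binding scores reject at the MHC stage with a warning.
    """
    out = []
    for cand in candidates:
        stage = _first_failing_stage(cand, config)
        if stage is None:
            out.append(replace(cand, verdict="selected", rejection_stage=None))
        else:
            if cand.scores is None:
                log.warning("candidate %s has no binding scores", cand.peptide.id)
            out.append(replace(cand, verdict="rejected", rejection_stage=stage))
    return out


def _first_failing_stage(cand: CandidateRecord, cfg: FunnelConfig) -> Optional[str]:
    s = cand.scores
    mhc_ok = s is not None and (
        s.mhc1_ic50 <= cfg.ic50_max_nM or s.mhc2_rank <= cfg.mhc2_rank_max
    )
    if not mhc_ok:
        return "mhc"
    if cand.snv.maf < cfg.maf_min_pct:
        return "maf"
    if (cand.snv.rna_mut_reads or 0) < cfg.rna_mut_reads_min:
        return "rna"
    return None


def funnel_report(candidates: Sequence) -> pd.DataFrame:
    """Table-shaped report: one row per candidate, selected rows numbered in
    input-rank order, rejected rows retained with their failing stage."""
    rows = []
    rank = 0
    for cand in candidates:
        if cand.verdict == "selected":
            rank += 1
        s = cand.scores
        rows.append(
            {
                "rank": rank if cand.verdict == "selected" else None,
                "id": cand.peptide.id,
                "gene": cand.peptide.gene_symbol,
                "sequence": cand.peptide.bracket,
                "rna_mut": cand.snv.rna_mut_reads,
                "rna_wt": cand.snv.rna_wt_reads,
                "maf_pct": cand.snv.maf,
                "ic50_nM": s.mhc1_ic50 if s else None,
                "mhc2_rank": s.mhc2_rank if s else None,
                "verdict": cand.verdict,
                "rejection_stage": cand.rejection_stage,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank", "id", "gene", "sequence", "rna_mut", "rna_wt", "maf_pct",
            "ic50_nM", "mhc2_rank", "verdict", "rejection_stage",
        ],
    )


def selected(candidates: Sequence) -> list:
    return [c for c in candidates if c.verdict == "selected"]
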