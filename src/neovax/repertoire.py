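"""TCR-beta repertoire statistics from clonotype-export tables.

Clonotype tables in the style of MiXCR exports (CDR3 sequence, clone read
count, V-hit column for chain inference) are reduced to two summary
statistics: the number of unique TCR-beta clonotypes, and the diversity
evenness DE50 — the minimum percentage of unique CDR3 clonotypes (reads
sorted descending) needed to account for 50% of the reads.  A perfectly even
repertoire has DE50 = 50%; a repertoire dominated by few clones approaches 0.

The DE50 denominator is the table's total clonotype reads (per-sample raw
TCR-mapping totals are not recoverable from a clonotype export).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_COLUMNS = {
    "count": "cloneCount",
    "cdr3_nt": "nSeqCDR3",
    "cdr3_aa": "aaSeqCDR3",
    "v_hits": "allVHitsWithScore",
}


@dataclass(frozen=True)
class ClonotypeTable:
    """Unique CDR3 clonotypes with read counts for one sample and chain."""

    sample: str
    chain: str
    clonotypes: pd.DataFrame  # columns: cdr3, reads

    def __post_init__(self) -> None:
        df = self.clonotypes
        if {"cdr3", "reads"} - set(df.columns):
            raise ValueError("clonotype frame needs columns cdr3, reads")
        if (df["reads"] < 1).any():
            raise ValueError("read counts must be >= 1")
        if df["cdr3"].duplicated().any():
            raise ValueError("duplicate CDR3 sequences after collapse")

    @property
    def n_clonotypes(self) -> int:
        return len(self.clonotypes)

    @property
    def total_reads(self) -> int:
        return int(self.clonotypes["reads"].sum())


@dataclass(frozen=True)
class RepertoireStats:
    sample: str
    n_clonotypes: int
    de50_pct: float


def read_clonotypes(
    path,
    chain: str = "TRB",
    sample: str = "",
    identity: str = "nt",
    columns: dict = None,
) -> ClonotypeTable:
    """Read a MiXCR-style clonotype TSV, keep one chain, collapse duplicates.

    Chain membership is inferred from the V-hit column (e.g. ``TRBV12-1*00``
    starts with the chain prefix) or, if present, a plain ``chain`` column.
    Clonotype identity is the CDR3 nucleotide sequence (``identity='nt'``)
    falling back to amino acid when the nucleotide column is absent; duplicate
    CDR3s are collapsed by summing reads.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"empty clonotype table: {path}")
    if cols["count"] not in df.columns:
        raise ValueError(
            f"missing clone-count column {cols['count']!r}; "
            f"available: {list(df.columns)}"
        )
    if identity == "nt" and cols["cdr3_nt"] in df.columns:
        cdr3_col = cols["cdr3_nt"]
    elif cols["cdr3_aa"] in df.columns:
        cdr3_col = cols["cdr3_aa"]
    else:
        raise ValueError(
            f"no CDR3 column among {cols['cdr3_nt']!r}/{cols['cdr3_aa']!r}; "
            f"available: {list(df.columns)}"
        )
    if "chain" in df.columns:
        mask = df["chain"].astype(str).str.upper().str.startswith(chain.upper())
    elif cols["v_hits"] in df.columns:
        mask = df[cols["v_hits"]].astype(str).str.upper().str.startswith(chain.upper())
    else:
        raise ValueError("no chain column and no V-hit column to infer the chain from")
    kept = df.loc[mask, [cdr3_col, cols["count"]]].rename(
        columns={cdr3_col: "cdr3", cols["count"]: "reads"}
    )
    if kept.empty:
        raise ValueError(f"no {chain} clonotypes in {path}")
    collapsed = (
        kept.groupby("cdr3", as_index=False)["reads"].sum().sort_values(
            ["reads", "cdr3"], ascending=[False, True], ignore_index=True
        )
    )
    return ClonotypeTable(sample=sample or str(path), chain=chain, clonotypes=collapsed)


def de50(table: ClonotypeTable) -> RepertoireStats:
    """Diversity evenness: minimal clonotype fraction covering half the reads.

    Counts are sorted descending (ties broken by CDR3 lexicographic order for
    determinism); ``k`` is the smallest prefix whose cumulative reads reach at
    least half the total (inclusive at exactly 50%), and DE50 = 100 * k / n.
    """
    if table.n_clonotypes == 0:
        raise ValueError("empty clonotype table")
    df = table.clonotypes.sort_values(
        ["reads", "cdr3"], ascending=[False, True], ignore_index=True
    )
    reads = df["reads"].to_numpy(dtype=float)
    cumulative = np.cumsum(reads)
    k = int(np.searchsorted(cumulative, 0.5 * reads.sum(), side="left")) + 1
    return RepertoireStats(
        sample=table.sample,
        n_clonotypes=table.n_clonotypes,
        de50_pct=100.0 * k / table.n_clonotypes,
    )


def repertoire_report(tables) -> pd.DataFrame:
    rows = []
    for t in tables:
        s = de50(t)
        rows.append(
            {
                "sample": s.sample,
                "chain": t.chain,
                "n_clonotypes": s.n_clonotypes,
                "total_reads": t.total_reads,
                "de50_pct": s.de50_pct,
            }
        )
    return pd.DataFrame(rows)
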