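"""Bulk expression analytics: TPM, gene filters, BH, consensus DEG voting,
gene-set overlap, hypergeometric enrichment, pathway coverage comparison.

Differential expression itself is delegated to external per-method result
tables (four methods in the study design); this module implements the
machinery that combines them: Benjamini-Hochberg adjustment per method, a
3-of-4 consensus vote with a median-log2FC magnitude rule, tumor-inflammation
signature overlap, upper-tail hypergeometric term enrichment with Bonferroni
correction, and the per-term coverage comparison between two response groups
by two-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DE_METHOD_COUNT = 4


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per kilobase million.

    ``counts`` is genes x samples, ``lengths`` the per-gene effective length
    in bases.  Per sample: rate_g = count_g / (length_g / 1000) and
    TPM_g = 1e6 * rate_g / sum(rates); every column sums to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing effective length for some genes")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rates = counts.div(lengths / 1000.0, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return rates.div(totals, axis=1) * 1e6


def filter_genes(
    counts: pd.DataFrame,
    tpm_matrix: pd.DataFrame,
    min_total_count: int = 10,
    min_tpm: float = 1.0,
    rule: str = "either",
) -> pd.Index:
    """Genes kept for differential-expression testing.

    Low-signal genes are excluded on total mapped-read count (< ``min_total_count``)
    and expression (best-sample TPM < ``min_tpm``).  ``rule='either'`` (default)
    excludes a gene failing either criterion; ``rule='both'`` excludes only
    genes failing both — the published phrasing is grammatically ambiguous, so
    the stricter reading is the default and the looser one stays available.
    """
    total_ok = counts.sum(axis=1) >= min_total_count
    tpm_ok = tpm_matrix.max(axis=1) >= min_tpm
    if rule == "either":
        keep = total_ok & tpm_ok
    elif rule == "both":
        keep = total_ok | tpm_ok
    else:
        raise ValueError(f"rule must be 'either' or 'both': {rule}")
    return counts.index[keep]


# ---------------------------------------------------------------------------
# Multiple testing and consensus vote
# ---------------------------------------------------------------------------


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class MethodDEResult:
    """One method's per-gene differential-expression table."""

    method: str
    table: pd.DataFrame  # index: gene; columns: log2fc, pvalue[, padj]

    def adjusted(self) -> pd.DataFrame:
        df = self.table.copy()
        if "padj" not in df.columns:
            df["padj"] = bh_adjust(df["pvalue"].to_numpy())
        return df


def read_method_table(path, method: str) -> MethodDEResult:
    """Per-method DE TSV (`gene log2fc pvalue`) -> result with BH column."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "log2fc", "pvalue"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return MethodDEResult(method=method, table=df.set_index("gene"))


def consensus_deg(
    results: Sequence,
    min_methods: int = 3,
    alpha: float = 0.05,
    lfc: float = 1.0,
) -> pd.DataFrame:
    """Cross-method consensus vote.

    A gene is retained when at least ``min_methods`` of the four methods flag
    it (BH-adjusted p <= ``alpha``) and the absolute median log2 fold change
    across all four methods exceeds ``lfc`` (strict).  Direction comes from
    the sign of the median.
    """
    if len(results) != DE_METHOD_COUNT:
        raise ValueError(f"expected {DE_METHOD_COUNT} method tables, got {len(results)}")
    tables = {r.method: r.adjusted() for r in results}
    genes = None
    for df in tables.values():
        genes = df.index if genes is None else genes.intersection(df.index)
        if len(df.index) != len(set(df.index)):
            raise ValueError("duplicate genes in a method table")
    genes = genes.sort_values()
    flags = pd.DataFrame(
        {m: df.loc[genes, "padj"] <= alpha for m, df in tables.items()}, index=genes
    )
    lfcs = pd.DataFrame(
        {m: df.loc[genes, "log2fc"] for m, df in tables.items()}, index=genes
    )
    median_lfc = lfcs.median(axis=1)
    n_flagging = flags.sum(axis=1)
    retained = (n_flagging >= min_methods) & (median_lfc.abs() > lfc)
    return pd.DataFrame(
        {
            "gene": genes,
            "n_methods_flagging": n_flagging.to_numpy(),
            "median_log2fc": median_lfc.to_numpy(),
            "direction": np.where(median_lfc.to_numpy() >= 0, "up", "down"),
            "retained": retained.to_numpy(),
        }
    ).reset_index(drop=True)


def signature_overlap(deg: pd.DataFrame, gene_set: Iterable) -> tuple:
    """(k, set size): gene-set members among retained upregulated genes."""
    members = set(gene_set)
    if not members:
        raise ValueError("empty gene set")
    up = set(deg.loc[deg["retained"] & (deg["direction"] == "up"), "gene"])
    return len(members & up), len(members)


# ---------------------------------------------------------------------------
# Enrichment and coverage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # overlap
    K: int  # term size (within universe)
    n: int  # query list size
    N: int  # universe size
    pvalue: float
    p_bonferroni: float

    @property
    def coverage_pct(self) -> float:
        return 100.0 * self.k / self.K


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for the hypergeometric overlap null."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    deg_genes: Iterable,
    annotation: Mapping,
    universe: Iterable,
    alpha: float = 0.05,
) -> list:
    """Per-term upper-tail hypergeometric enrichment with Bonferroni.

    The universe should be the filtered (tested) gene set, not the whole
    annotation.  Terms with no gene in the universe are not tested; the
    Bonferroni factor is the number of tested terms.  Results are sorted by
    adjusted then raw p; the ``alpha`` threshold is the caller's reporting
    cutoff (0.05 or 0.01 in the study's two analyses) and is not applied here.
    """
    universe = set(universe)
    query = set(deg_genes)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(universe), len(query)
    tested = []
    for term in sorted(annotation):
        term_genes = set(annotation[term]) & universe
        if not term_genes:
            continue
        k = len(term_genes & query)
        tested.append((term, k, len(term_genes)))
    m = len(tested)
    out = []
    for term, k, K in tested:
        p = hypergeom_tail(k, N, K, n)
        out.append(
            EnrichmentResult(
                term=term, k=k, K=K, n=n, N=N,
                pvalue=p, p_bonferroni=min(1.0, p * m),
            )
        )
    out.sort(key=lambda r: (r.p_bonferroni, r.pvalue, r.term))
    return out


def enrichment_table(results: Sequence) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "pvalue": r.pvalue, "p_bonferroni": r.p_bonferroni,
                "coverage_pct": r.coverage_pct,
            }
            for r in results
        ]
    )


def coverage_and_compare(
    term_genes: Iterable,
    modulated_a: Iterable,
    modulated_b: Iterable,
    min_coverage_pct: float = 40.0,
) -> dict:
    """Per-group term coverage and a two-sided Fisher comparison.

    Coverage is the percentage of the term's genes modulated in each group;
    the 2x2 table (modulated / not, by group) is tested with a two-sided
    Fisher exact test.  ``passes_coverage`` applies the reporting rule that
    at least ``min_coverage_pct`` of the term's genes are modulated in the
    first group (inclusive).
    """
    term = set(term_genes)
    if not term:
        raise ValueError("empty term gene set")
    ka = len(term & set(modulated_a))
    kb = len(term & set(modulated_b))
    K = len(term)
    table = [[ka, K - ka], [kb, K - kb]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    cov_a = 100.0 * ka / K
    cov_b = 100.0 * kb / K
    return {
        "term_size": K,
        "k_a": ka,
        "k_b": kb,
        "coverage_a_pct": cov_a,
        "coverage_b_pct": cov_b,
        "fisher_p": float(p),
        "passes_coverage": cov_a >= min_coverage_pct,
    }


def read_gmt(path) -> dict:
    """GMT-style annotation: ``term<TAB>description<TAB>gene...`` per line."""
    terms = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]}...")
            terms[fields[0]] = set(g for g in fields[2:] if g)
    return terms
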