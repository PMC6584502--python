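"""TPM, gene filters, BH step-up, consensus vote, enrichment, Fisher comparison."""

import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest

from neovax import simulate
from neovax.omics import (
    MethodDEResult,
    bh_adjust,
    consensus_deg,
    coverage_and_compare,
    enrich,
    filter_genes,
    hypergeom_tail,
    read_gmt,
    signature_overlap,
    tpm,
)

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def bh_oracle(pvals):
    """Literal step-up: adj_(i) = min_{j>=i} p_(j) * m / j, clipped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = min(1.0, running)
    return adj


def hypergeom_oracle(k, N, K, n):
    """P(X >= k) by summing exact hypergeometric point masses."""
    denom = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    ) / denom


def fisher_oracle(table):
    """Two-sided Fisher exact p by enumerating all tables with fixed margins."""
    (a, b), (c, d) = table
    row1, col1, total = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(row1, x)
            * math.comb(total - row1, col1 - x)
            / math.comb(total, col1)
        )

    p_obs = prob(a)
    lo, hi = max(0, col1 - (total - row1)), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------


class TestTpm:
    def test_hand_computed_two_genes(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        lengths = pd.Series([1000, 2000], index=["g1", "g2"])
        out = tpm(counts, lengths)
        assert out["s1"].tolist() == pytest.approx([666666.67, 333333.33], abs=0.01)

    def test_equal_counts_and_lengths_split_evenly(self):
        counts = pd.DataFrame({"s1": [7, 7, 7, 7]}, index=list("abcd"))
        lengths = pd.Series([500] * 4, index=list("abcd"))
        assert tpm(counts, lengths)["s1"].tolist() == pytest.approx([250000.0] * 4)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(40, 5)), index=[f"g{i}" for i in range(40)]
        )
        counts.iloc[0] += 1  # avoid an all-zero sample
        lengths = pd.Series(rng.integers(200, 5000, size=40), index=counts.index)
        out = tpm(counts, lengths)
        assert np.allclose(out.sum(axis=0), 1e6, rtol=1e-9)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="all-zero"):
            tpm(counts, pd.Series([100, 100], index=["g1", "g2"]))


class TestFilterGenes:
    def make(self, total, max_tpm):
        counts = pd.DataFrame({"s1": [total]}, index=["g"])
        tpm_m = pd.DataFrame({"s1": [max_tpm]}, index=["g"])
        return counts, tpm_m

    @pytest.mark.parametrize(
        "total,max_tpm,kept",
        [(9, 5.0, False), (100, 0.5, False), (100, 3.0, True), (10, 1.0, True)],
    )
    def test_either_failure_excludes(self, total, max_tpm, kept):
        counts, tpm_m = self.make(total, max_tpm)
        assert ("g" in filter_genes(counts, tpm_m)) == kept

    def test_loose_rule_keeps_single_failures(self):
        counts, tpm_m = self.make(9, 5.0)
        assert "g" in filter_genes(counts, tpm_m, rule="both")


class TestBhAdjust:
    def test_two_value_step_up(self):
        assert bh_adjust([0.01, 0.04]).tolist() == pytest.approx([0.02, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_uniform_ladder_collapses(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx([0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = random.Random(19)
        for _ in range(2000):
            p = [rng.random() for _ in range(rng.randint(1, 50))]
            assert bh_adjust(p).tolist() == pytest.approx(bh_oracle(p))
            assert all(a >= x for a, x in zip(bh_adjust(p), p))  # adjusted >= raw


def method_tables(lfcs, significant, genes=("gA",)):
    """Four single-gene method tables with chosen log2FCs and significance."""
    out = []
    for i, (lfc, sig) in enumerate(zip(lfcs, significant)):
        df = pd.DataFrame(
            {"log2fc": [lfc], "padj": [0.01 if sig else 0.5], "pvalue": [0.01 if sig else 0.5]},
            index=list(genes),
        )
        df.index.name = "gene"
        out.append(MethodDEResult(f"m{i}", df))
    return out


class TestConsensusDeg:
    def test_three_votes_and_median_above_one_retained(self):
        res = consensus_deg(method_tables((1.5, 1.2, 0.9, 1.1), (True, True, True, False)))
        row = res.iloc[0]
        assert row["n_methods_flagging"] == 3
        assert row["median_log2fc"] == pytest.approx(1.15)
        assert row["retained"] and row["direction"] == "up"

    def test_two_votes_insufficient(self):
        res = consensus_deg(method_tables((2.0, 2.0, 2.0, 2.0), (True, True, False, False)))
        assert not res.iloc[0]["retained"]

    def test_median_magnitude_rule_is_strict(self):
        res = consensus_deg(method_tables((0.9, 0.95, 1.0, 0.8), (True,) * 4))
        assert res.iloc[0]["median_log2fc"] == pytest.approx(0.925)
        assert not res.iloc[0]["retained"]

    def test_downregulated_direction(self):
        res = consensus_deg(method_tables((-1.5, -1.4, -1.6, -1.2), (True,) * 4))
        assert res.iloc[0]["retained"] and res.iloc[0]["direction"] == "down"

    def test_requires_exactly_four_methods(self):
        with pytest.raises(ValueError, match="4 method"):
            consensus_deg(method_tables((1.0, 1.0), (True, True))[:2])

    def test_planted_truth_recovered_on_synthetic_tables(self):
        tables, truth = simulate.simulate_de_tables(800, 40, effect=2.0, seed=23)
        results = [MethodDEResult(m, df.set_index("gene")) for m, df in tables.items()]
        res = consensus_deg(results)
        got = set(res.loc[res["retained"], "gene"])
        assert not got - set(truth)  # zero false positives
        assert len(got) >= 0.9 * len(truth)


class TestSignatureOverlap:
    def deg(self, up, down=(), null=()):
        rows = (
            [(g, 4, 2.0, "up", True) for g in up]
            + [(g, 4, -2.0, "down", True) for g in down]
            + [(g, 1, 0.1, "up", False) for g in null]
        )
        return pd.DataFrame(
            rows, columns=["gene", "n_methods_flagging", "median_log2fc", "direction", "retained"]
        )

    def test_counts_set_members_among_up_genes(self):
        deg = self.deg(up=[f"t{i}" for i in range(15)] + ["x1", "x2"])
        gene_set = [f"t{i}" for i in range(15)] + ["absent1", "absent2", "absent3"]
        assert signature_overlap(deg, gene_set) == (15, 18)

    def test_disjoint_and_subset_cases(self):
        deg = self.deg(up=["a", "b"], down=["c"])
        assert signature_overlap(deg, ["z1", "z2"]) == (0, 2)
        assert signature_overlap(deg, ["a", "b"]) == (2, 2)
        assert signature_overlap(deg, ["c"]) == (0, 1)  # down genes do not count

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            signature_overlap(self.deg(up=["a"]), [])


class TestEnrichment:
    def test_exact_small_example(self):
        # N=20, K=5, n=5, k=4 -> P(X>=4) = 76/15504
        universe = [f"g{i}" for i in range(20)]
        annotation = {"term": universe[:5]}
        query = universe[:4] + [universe[10]]
        (res,) = enrich(query, annotation, universe)
        assert (res.k, res.K, res.n, res.N) == (4, 5, 5, 20)
        assert res.pvalue == pytest.approx(76 / 15504)
        assert res.p_bonferroni == pytest.approx(76 / 15504)  # single term: m=1

    def test_zero_overlap_has_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        (res,) = enrich(universe[5:7], {"t": universe[:3]}, universe)
        assert res.k == 0 and res.pvalue == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            enrich(["alien"], {"t": ["g1"]}, ["g1", "g2"])

    def test_bonferroni_never_below_raw(self):
        universe = [f"g{i}" for i in range(30)]
        annotation = {f"t{j}": universe[j : j + 6] for j in range(10)}
        results = enrich(universe[:5], annotation, universe)
        assert all(r.p_bonferroni >= r.pvalue for r in results)

    def test_tail_matches_exhaustive_enumeration(self):
        for N in (5, 10, 25):
            for K in range(0, N + 1, max(1, N // 4)):
                for n in range(0, N + 1, max(1, N // 4)):
                    for k in range(0, min(K, n) + 1):
                        assert hypergeom_tail(k, N, K, n) == pytest.approx(
                            hypergeom_oracle(k, N, K, n), abs=1e-12
                        )

    def test_coverage_percentage(self):
        universe = [f"g{i}" for i in range(50)]
        annotation = {"t": universe[:20]}
        results = enrich(universe[:8], annotation, universe)
        assert results[0].coverage_pct == pytest.approx(40.0)


class TestCoverageAndCompare:
    def test_maximally_different_groups(self):
        term = [f"g{i}" for i in range(5)]
        out = coverage_and_compare(term, modulated_a=term, modulated_b=[])
        assert out["fisher_p"] == pytest.approx(2 / 252)
        assert out["coverage_a_pct"] == 100.0 and out["coverage_b_pct"] == 0.0

    def test_identical_groups_give_p_one(self):
        term = [f"g{i}" for i in range(6)]
        out = coverage_and_compare(term, term[:3], term[:3])
        assert out["fisher_p"] == pytest.approx(1.0)

    def test_forty_percent_coverage_rule_inclusive(self):
        term = [f"g{i}" for i in range(20)]
        out = coverage_and_compare(term, term[:8], term[:2])
        assert out["coverage_a_pct"] == pytest.approx(40.0)
        assert out["passes_coverage"]

    def test_empty_term_rejected(self):
        with pytest.raises(ValueError):
            coverage_and_compare([], ["a"], ["b"])

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = random.Random(29)
        for _ in range(100):
            K = rng.randint(2, 12)
            term = [f"g{i}" for i in range(K)]
            ka, kb = rng.randint(0, K), rng.randint(0, K)
            out = coverage_and_compare(term, term[:ka], term[:kb])
            assert out["fisher_p"] == pytest.approx(
                fisher_oracle([[ka, K - ka], [kb, K - kb]]), rel=1e-9
            )


class TestReadGmt:
    def test_gmt_parsing(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("tis\tinflammation signature\tCd2\tCd3e\tLag3\n")
        assert read_gmt(path) == {"tis": {"Cd2", "Cd3e", "Lag3"}}

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_one_field\n")
        with pytest.raises(ValueError):
            read_gmt(path)
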