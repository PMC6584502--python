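"""SNV reading, two-caller union-merge, and codon-level annotation."""

import logging
import random

import pytest
from Bio.Seq import Seq

from neovax import variants
from neovax.variants import (
    CodingEffect,
    ReferenceMismatchError,
    SomaticSNV,
    TranscriptModel,
    annotate_coding,
    attach_rna_counts,
    read_snv_calls,
    union_merge,
)


def snv(chrom="chr1", pos=100, ref="A", alt="C", maf=50.0, caller="x", **kw):
    return SomaticSNV(chrom, pos, ref, alt, maf, frozenset({caller}), **kw)


class TestReadSnvCalls:
    def test_af_field_maps_to_percent_maf(self, vcf_writer):
        path = vcf_writer("a.vcf", [(100, "A", "G", 0.57), (200, "C", "T", 0.30)])
        calls = read_snv_calls(path, "mutect")
        assert [(c.pos, c.maf) for c in calls] == [(100, 57.0), (200, 30.0)]
        assert all(c.callers == frozenset({"mutect"}) for c in calls)

    def test_non_snv_records_skipped_with_logged_count(self, vcf_writer, caplog):
        path = vcf_writer(
            "b.vcf",
            [(100, "A", "G", 0.5), (200, "AT", "A", 0.5), (300, "AT", "GC", 0.4)],
        )
        with caplog.at_level(logging.INFO, logger="neovax.variants"):
            calls = read_snv_calls(path, "mutect")
        assert len(calls) == 1 and calls[0].pos == 100
        assert "skipped 2 non-SNV" in caplog.text

    def test_missing_af_names_locus(self, tmp_path):
        path = tmp_path / "c.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t123\t.\tA\tG\t.\tPASS\t.\n"
        )
        with pytest.raises(ValueError, match="chr1:123"):
            read_snv_calls(path, "mutect")


class TestSomaticSNVInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(ref="A", alt="A"),
            dict(ref="N", alt="C"),
            dict(maf=120.0),
            dict(maf=-1.0),
            dict(rna_mut_reads=-1),
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        base = dict(chrom="chr1", pos=1, ref="A", alt="C", maf=50.0,
                    callers=frozenset({"x"}))
        base.update(kwargs)
        with pytest.raises(ValueError):
            SomaticSNV(**base)

    def test_empty_callers_rejected(self):
        with pytest.raises(ValueError):
            SomaticSNV("chr1", 1, "A", "C", 50.0, frozenset())


class TestUnionMerge:
    def test_disjoint_inputs_concatenate(self):
        a = [snv(pos=1), snv(pos=2)]
        b = [snv(pos=3, caller="y"), snv(pos=4, caller="y"), snv(pos=5, caller="y")]
        merged = union_merge(a, b)
        assert len(merged) == 5
        assert all(len(m.callers) == 1 for m in merged)

    def test_identical_inputs_union_labels(self):
        a = [snv(pos=1, caller="x"), snv(pos=2, caller="x")]
        b = [snv(pos=1, caller="y"), snv(pos=2, caller="y")]
        merged = union_merge(a, b)
        assert len(merged) == 2
        assert all(m.callers == frozenset({"x", "y"}) for m in merged)

    def test_partial_overlap(self):
        a = [snv(pos=1), snv(pos=2)]
        b = [snv(pos=2, caller="y"), snv(pos=3, caller="y")]
        merged = union_merge(a, b)
        assert len(merged) == 3
        shared = [m for m in merged if m.pos == 2]
        assert len(shared[0].callers) == 2

    def test_shared_variant_takes_max_maf(self):
        merged = union_merge([snv(maf=30.0)], [snv(maf=45.0, caller="y")])
        assert merged[0].maf == 45.0

    def test_conflicting_rna_counts_name_locus(self):
        a = [snv(rna_mut_reads=5)]
        b = [snv(rna_mut_reads=9, caller="y")]
        with pytest.raises(ValueError, match="chr1:100"):
            union_merge(a, b)

    def test_matches_brute_force_set_union_and_is_commutative(self):
        rng = random.Random(42)
        for _ in range(300):
            keys = [("chr1", p, "A", "C") for p in range(1, 13)]
            ka = rng.sample(keys, rng.randint(0, 8))
            kb = rng.sample(keys, rng.randint(0, 8))
            a = [snv(pos=k[1]) for k in ka]
            b = [snv(pos=k[1], caller="y") for k in kb]
            merged = union_merge(a, b)
            expected = {k[1] for k in ka} | {k[1] for k in kb}
            assert {m.pos for m in merged} == expected
            assert max(len(ka), len(kb)) <= len(merged) <= len(ka) + len(kb)
            # commutative and idempotent on keys
            assert {m.pos for m in union_merge(b, a)} == expected
            assert {m.pos for m in union_merge(merged, merged)} == expected


class TestAttachRnaCounts:
    def test_counts_keyed_on_locus(self):
        counts = {("chr1", 100, "A", "C"): (7, 3)}
        (out,) = attach_rna_counts([snv()], counts)
        assert (out.rna_mut_reads, out.rna_wt_reads) == (7, 3)

    def test_missing_locus_defaults_to_zero(self, caplog):
        with caplog.at_level(logging.WARNING, logger="neovax.variants"):
            (out,) = attach_rna_counts([snv()], {})
        assert (out.rna_mut_reads, out.rna_wt_reads) == (0, 0)
        assert "no RNA counts" in caplog.text


def model_for(cds, chrom="chr1", start=11, strand="+", tid="t1", gene="G1"):
    return TranscriptModel(
        transcript_id=tid,
        gene_symbol=gene,
        chrom=chrom,
        strand=strand,
        cds_blocks=((start, start + len(cds) - 1),),
    )


class TestAnnotateCoding:
    # a 10-base pad on each side keeps the CDS internal to the contig
    PAD = "GGGGGGGGGG"

    def genome(self, cds):
        return {"chr1": self.PAD + cds + self.PAD}

    def test_missense_call_matches_codon_table(self):
        cds = "ATGGATTAA"
        eff = annotate_coding(
            snv(pos=14, ref="G", alt="T"), model_for(cds), self.genome(cds)
        )
        assert (eff.wt_aa, eff.mut_aa, eff.effect_class, eff.protein_pos) == (
            "D", "Y", "missense", 2,
        )

    def test_degenerate_codon_is_synonymous(self):
        cds = "ATGGATTAA"
        eff = annotate_coding(
            snv(pos=16, ref="T", alt="C"), model_for(cds), self.genome(cds)
        )
        assert (eff.wt_aa, eff.mut_aa, eff.effect_class) == ("D", "D", "synonymous")

    def test_stop_gain_is_nonsense(self):
        cds = "ATGGAATAA"
        eff = annotate_coding(
            snv(pos=14, ref="G", alt="T"), model_for(cds), self.genome(cds)
        )
        assert (eff.wt_aa, eff.mut_aa, eff.effect_class) == ("E", "*", "nonsense")

    def test_position_outside_cds_returns_none(self):
        cds = "ATGGATTAA"
        assert annotate_coding(snv(pos=5, ref="G", alt="T"),
                               model_for(cds), self.genome(cds)) is None

    def test_reference_mismatch_raises(self):
        cds = "ATGGATTAA"
        with pytest.raises(ReferenceMismatchError, match="chr1:14"):
            annotate_coding(snv(pos=14, ref="C", alt="T"),
                            model_for(cds), self.genome(cds))

    def test_minus_strand_equals_plus_strand_oracle(self):
        """Annotating a minus-strand transcript must agree with annotating the
        reverse-complemented plus-strand equivalent."""
        rng = random.Random(7)
        comp = str.maketrans("ACGT", "TGCA")
        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                  if str(Seq(a + b + c).translate()) != "*"]
        for _ in range(50):
            cds = "ATG" + "".join(rng.choice(codons) for _ in range(10)) + "TAA"
            idx = rng.randrange(3, len(cds) - 3)  # skip start/stop codons
            ref = cds[idx]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            # plus-strand layout
            plus_eff = annotate_coding(
                snv(pos=11 + idx, ref=ref, alt=alt),
                model_for(cds, strand="+"),
                self.genome(cds),
            )
            # minus-strand layout: genome carries the reverse complement
            rc = cds.translate(comp)[::-1]
            minus_idx = len(cds) - 1 - idx
            minus_eff = annotate_coding(
                snv(pos=11 + minus_idx, ref=ref.translate(comp), alt=alt.translate(comp)),
                model_for(rc, strand="-"),
                self.genome(rc),
            )
            assert plus_eff is not None and minus_eff is not None
            assert (plus_eff.wt_aa, plus_eff.mut_aa, plus_eff.protein_pos,
                    plus_eff.effect_class) == (
                minus_eff.wt_aa, minus_eff.mut_aa, minus_eff.protein_pos,
                minus_eff.effect_class,
            )

    def test_effect_reproduced_by_translating_mutated_cds(self):
        rng = random.Random(13)
        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                  if str(Seq(a + b + c).translate()) != "*"]
        checked = 0
        for _ in range(200):
            cds = "ATG" + "".join(rng.choice(codons) for _ in range(15)) + "TAA"
            idx = rng.randrange(len(cds))
            ref = cds[idx]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            eff = annotate_coding(
                snv(pos=11 + idx, ref=ref, alt=alt), model_for(cds), self.genome(cds)
            )
            mutated = cds[:idx] + alt + cds[idx + 1 :]
            wt_prot = str(Seq(cds).translate())
            mut_prot = str(Seq(mutated).translate())
            assert wt_prot[eff.protein_pos - 1] == eff.wt_aa
            assert mut_prot[eff.protein_pos - 1] == eff.mut_aa
            checked += 1
        assert checked == 200


class TestTranscriptModel:
    def test_cds_length_must_be_multiple_of_three(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            TranscriptModel("t1", "G", "chr1", "+", ((1, 10),))

    def test_blocks_must_be_sorted_and_disjoint(self):
        with pytest.raises(ValueError, match="overlap"):
            TranscriptModel("t1", "G", "chr1", "+", ((10, 15), (12, 17)))

    def test_split_cds_concatenates_blocks(self):
        genome = {"chr1": "NNATGGATNNNNTAANN"}
        m = TranscriptModel("t1", "G", "chr1", "+", ((3, 8), (13, 15)))
        assert m.cds_sequence(genome) == "ATGGATTAA"
        assert m.protein_sequence(genome) == "MD"

    def test_missense_invariant_on_coding_effect(self):
        with pytest.raises(ValueError, match="missense"):
            CodingEffect(snv(), "t1", "G", 1, "D", "D", "missense")
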