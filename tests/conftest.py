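"""Shared fixtures: a seeded synthetic mutanome bundle and small file writers."""

import textwrap

import pytest

from neovax import funnel, pipeline, simulate

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID={chrom},length=100000>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=AF,Number=A,Type=Float,Description="Tumor allele fraction">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR
    """
)


def write_vcf(path, records, chrom="chr1"):
    """records: iterable of (pos, ref, alt, af) on one contig."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(chrom=chrom))
        for pos, ref, alt, af in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AF\t0/1:{af}\n")
    return path


@pytest.fixture
def vcf_writer(tmp_path):
    def _write(name, records, chrom="chr1"):
        return write_vcf(tmp_path / name, records, chrom=chrom)

    return _write


@pytest.fixture(scope="session")
def mutanome_bundle(tmp_path_factory):
    cfg = simulate.SimulationConfig(seed=11)
    bundle = simulate.simulate_mutanome(cfg, tmp_path_factory.mktemp("mutanome"))
    return cfg, bundle


@pytest.fixture(scope="session")
def selection_result(mutanome_bundle):
    """Full pipeline run on the session bundle, using its binding table."""
    cfg, bundle = mutanome_bundle
    predictor = funnel.TableBindingPredictor.from_tsv(bundle.binding_tsv)
    result = pipeline.select_neoantigens(
        bundle.vcf_a,
        bundle.vcf_b,
        bundle.transcripts_gff3,
        bundle.genome_fasta,
        bundle.rna_counts_tsv,
        predictor,
        caller_labels=cfg.caller_labels,
    )
    return bundle, result
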