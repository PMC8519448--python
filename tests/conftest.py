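import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hapmotif import fixtures as fx
from hapmotif import genome_graph as gg


@pytest.fixture
def snp_graph():
    """ref ACGTACGT with a het SNP T>G at pos 4 (sample S1, 0|1)."""
    vr = gg.VariantRecord(
        chrom="chr1",
        pos=4,
        ref_allele="T",
        alt_alleles=("G",),
        genotypes={"S1": (0, 1, True)},
    )
    return gg.build_graph("ACGTACGT", [vr], chrom="chr1")


@pytest.fixture
def two_snp_graph():
    """Two het SNPs phased so only haplotypes 0-0 and 1-1 are observed."""
    ref = "ACGTACGTACGT"
    v1 = gg.VariantRecord(
        chrom="chr1", pos=4, ref_allele="T", alt_alleles=("G",),
        genotypes={"S1": (0, 1, True)},
    )
    v2 = gg.VariantRecord(
        chrom="chr1", pos=9, ref_allele="A", alt_alleles=("C",),
        genotypes={"S1": (0, 1, True)},
    )
    return gg.build_graph(ref, [v1, v2], chrom="chr1"), ref


@pytest.fixture(scope="session")
def toy_pwm():
    return fx.make_consensus_pwm("ACGGTAAC", "TOY1", "TOY")


@pytest.fixture(scope="session")
def planted_dataset(tmp_path_factory, toy_pwm):
    """Seeded fixture with one alt-branch-only planted site and one ref site."""
    out = tmp_path_factory.mktemp("planted")
    return fx.make_toy_dataset(
        seed=11,
        out_dir=str(out),
        chrom_len=1200,
        n_samples=4,
        n_snps=6,
        n_indels=2,
        planted=[
            fx.PlantedSite(toy_pwm, 300, "alt"),
            fx.PlantedSite(toy_pwm, 600, "ref"),
        ],
    )


@pytest.fixture(scope="session")
def planted_graph(planted_dataset):
    import warnings

    samples, by_chrom = gg.read_vcf(planted_dataset.vcf_path)
    seqs = gg.read_fasta(planted_dataset.fasta_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gg.build_graph(
            seqs[planted_dataset.chrom],
            by_chrom.get(planted_dataset.chrom, []),
            chrom=planted_dataset.chrom,
            samples=samples,
        )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
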