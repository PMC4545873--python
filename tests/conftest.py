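import numpy as np
import pytest

from sweepscan.datatypes import HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_haplotype_matrix(
    rng, n_hap=12, n_sites=30, span=100_000, n_focal=None, chrom="chr1"
):
    """Random biallelic phased matrix with focal/reference labels."""
    if n_focal is None:
        n_focal = n_hap // 2
    alleles = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.uint8)
    positions = np.sort(rng.choice(span, size=n_sites, replace=False))
    hap_pop = np.array(["focal"] * n_focal + ["reference"] * (n_hap - n_focal))
    return HaplotypeMatrix(chrom, positions, alleles, hap_pop)


@pytest.fixture
def small_vcf(tmp_path):
    """Two samples, three phased biallelic SNPs, plus excluded records."""
    text = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\tS1
chr1\t101\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1
chr1\t200\t.\tG\tC\t.\tPASS\t.\tGT\t0|0\t0|1
chr1\t300\t.\tA\tT,G\t.\tPASS\t.\tGT\t0|1\t0|2
chr1\t400\t.\tC\tA\t.\tPASS\t.\tGT\t0/1\t1|1
chr1\t500\t.\tT\tG\t.\tPASS\t.\tGT\t.|.\t0|1
chr1\t600\t.\tT\tC\t.\tPASS\t.\tGT\t1|0\t0|0
"""
    path = tmp_path / "small.vcf"
    path.write_text(text)
    popmap = tmp_path / "popmap.tsv"
    popmap.write_text("S0\tfocal\nS1\treference\n")
    return path, popmap
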