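import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bsamap import MarkerTrack

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_track(chrom="chr1", n=60, seed=0, depth_low=20, depth_high=120):
    """Random but valid marker track with moderate depths."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, n * 1000), size=n, replace=False))
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, n)
    alt_i = (ref_i + rng.integers(1, 4, n)) % 4
    wt_depth = rng.integers(depth_low, depth_high + 1, n)
    mut_depth = rng.integers(depth_low, depth_high + 1, n)
    wt_alt = rng.binomial(wt_depth, 0.5)
    mut_alt = rng.binomial(mut_depth, 0.5)
    return MarkerTrack(
        chrom, pos, bases[ref_i], bases[alt_i],
        wt_depth - wt_alt, wt_alt, mut_depth - mut_alt, mut_alt,
    )


@pytest.fixture
def random_track():
    return build_track()


VCF_TEXT = """\
##fileformat=VCFv4.2
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr2,length=19700000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\twt_pool\tmut_pool
chr2\t100\t.\tG\tA\t.\t.\t.\tAD\t30,10\t0,40
chr2\t200\t.\tC\tT\t.\t.\t.\tAD\t25,25\t10,30
chr2\t300\t.\tG\tA,T\t.\t.\t.\tAD\t10,10,10\t10,10,10
chr2\t400\t.\tGT\tG\t.\t.\t.\tAD\t20,20\t20,20
chr2\t500\t.\tA\tC\t.\t.\t.\tGT\t0/1\t1/1
chr2\t600\t.\tT\tC\t.\t.\t.\tAD\t15,30\t5,50
"""


@pytest.fixture
def pooled_vcf(tmp_path):
    path = tmp_path / "pools.vcf"
    path.write_text(VCF_TEXT)
    return path


GFF_TEXT = """\
##gff-version 3
chr2\ttest\tgene\t1000\t1400\t.\t+\t.\tID=geneA
chr2\ttest\tmRNA\t1000\t1400\t.\t+\t.\tID=mRNA_A;Parent=geneA
chr2\ttest\texon\t1000\t1100\t.\t+\t.\tID=exA1;Parent=mRNA_A
chr2\ttest\texon\t1201\t1300\t.\t+\t.\tID=exA2;Parent=mRNA_A
chr2\ttest\texon\t1351\t1400\t.\t+\t.\tID=exA3;Parent=mRNA_A
chr2\ttest\tgene\t2000\t2300\t.\t-\t.\tID=geneB
chr2\ttest\tmRNA\t2000\t2300\t.\t-\t.\tID=mRNA_B;Parent=geneB
chr2\ttest\texon\t2000\t2100\t.\t-\t.\tID=exB1;Parent=mRNA_B
chr2\ttest\texon\t2201\t2300\t.\t-\t.\tID=exB2;Parent=mRNA_B
chr2\ttest\tgene\t3000\t3100\t.\t+\t.\tID=geneC
chr2\ttest\tmRNA\t3000\t3100\t.\t+\t.\tID=mRNA_C;Parent=geneC
chr2\ttest\texon\t3000\t3100\t.\t+\t.\tID=exC1;Parent=mRNA_C
chr2\ttest\tgene\t4000\t4300\t.\t+\t.\tID=geneD
chr2\ttest\tmRNA\t4000\t4300\t.\t+\t.\tID=mRNA_D;Parent=geneD
chr2\ttest\texon\t4000\t4200\t.\t+\t.\tID=exD1;Parent=mRNA_D
chr2\ttest\texon\t4100\t4300\t.\t+\t.\tID=exD2;Parent=mRNA_D
"""


@pytest.fixture
def gff3_file(tmp_path):
    path = tmp_path / "genes.gff3"
    path.write_text(GFF_TEXT)
    return path
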