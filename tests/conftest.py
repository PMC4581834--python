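import numpy as np
import pytest

from hafscore import HaplotypeMatrix


@pytest.fixture
def hand_matrix():
    """4 haplotypes x 3 polymorphic sites with hand-computed scores.

    Column derived counts are (3, 1, 1); HAF vectors
    c1=[3,1,0], c2=[3,0,1], c3=[3,0,0], c4=[0,0,0].
    """
    return HaplotypeMatrix(
        data=[[1, 1, 0], [1, 0, 1], [1, 0, 0], [0, 0, 0]],
        positions=[10.0, 20.0, 30.0],
    )


TOY_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t1|1\t0|0
1\t200\t.\tC\tT\t.\tPASS\tAA=T\tGT\t0|1\t0|0\t1|1
1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t0|0\t0|1\t0|0
1\t400\t.\tT\tC\t.\tPASS\tAA=T\tGT\t0|1\t0|1\t0|1
"""


@pytest.fixture
def toy_vcf(tmp_path):
    """3 phased diploid samples, 4 sites; site 300 lacks an ancestral call."""
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20_150_924)
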