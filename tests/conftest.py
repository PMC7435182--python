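import numpy as np
import pytest

from bsrmap import GeneModel, MarkerGenotypeTable

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=A01,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tmutpool\twtpool
A01\t100\t.\tC\tT\t50\tPASS\t.\tGT:AD\t1/1:0,10\t0/1:5,5
A01\t200\t.\tG\tA\t50\tPASS\t.\tGT:AD\t0/1:3,7\t0/0:9,1
A01\t300\t.\tA\tG\t50\tPASS\t.\tGT:AD\t0/1:6,6\t0/1:4,8
"""

TOY_VCF_MULTIALLELIC = TOY_VCF + "A01\t400\t.\tC\tT,G\t50\tPASS\t.\tGT:AD\t1/2:1,4,5\t0/1:5,5,0\n"


@pytest.fixture
def toy_vcf(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p


@pytest.fixture
def toy_vcf_multi(tmp_path):
    p = tmp_path / "toy_multi.vcf"
    p.write_text(TOY_VCF_MULTIALLELIC)
    return p


@pytest.fixture
def toy_variant_table(tmp_path):
    p = tmp_path / "toy.tsv"
    p.write_text(
        "chrom\tpos\tref\talt\tmut_ref\tmut_alt\twt_ref\twt_alt\n"
        "A01\t100\tC\tT\t0\t10\t5\t5\n"
        "A01\t200\tG\tA\t3\t7\t9\t1\n"
        "A01\t300\tA\tG\t6\t6\t4\t8\n"
    )
    return p


# A two-exon gene on a 60 bp toy chromosome, CDS = 11-25 plus 31-45:
# ATG GCT ACT AAA GGG | CCC TTT GGG ACT TAA  (10 codons, stop at the end)
TOY_SEQ = "N" * 10 + "ATGGCTACTAAAGGG" + "NNNNN" + "CCCTTTGGGACTTAA" + "N" * 15


@pytest.fixture
def toy_genome():
    return {"A01": TOY_SEQ}


@pytest.fixture
def toy_gene():
    return GeneModel("G1", "A01", "+", 11, 45, [(11, 25), (31, 45)])


@pytest.fixture
def toy_gff3(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(
        "##gff-version 3\n"
        "A01\ttest\tgene\t11\t45\t.\t+\t.\tID=G1\n"
        "A01\ttest\tmRNA\t11\t45\t.\t+\t.\tID=G1.1;Parent=G1\n"
        "A01\ttest\tCDS\t11\t25\t.\t+\t0\tID=G1.1.cds1;Parent=G1.1\n"
        "A01\ttest\tCDS\t31\t45\t.\t+\t0\tID=G1.1.cds2;Parent=G1.1\n"
    )
    return p


@pytest.fixture
def toy_bed12(tmp_path):
    # same gene: chromStart 10, blocks (0,15) and (20,15), thick = full span
    p = tmp_path / "toy.bed"
    p.write_text("A01\t10\t45\tG1\t0\t+\t10\t45\t0\t2\t15,15\t0,20\n")
    return p


def make_marker_table(calls, markers=None, pos=None, recessive_only=True):
    """Build a MarkerGenotypeTable from a list of call strings (one per
    individual, one character per marker)."""
    calls = np.array([list(row) for row in calls])
    n_ind, n_mark = calls.shape
    markers = markers or [f"M{j}" for j in range(n_mark)]
    pos = pos or [(j + 1) * 1000 for j in range(n_mark)]
    return MarkerGenotypeTable(
        individuals=[f"ind{i}" for i in range(n_ind)],
        markers=markers,
        marker_chroms=["A01"] * n_mark,
        marker_pos=pos,
        calls=calls,
        recessive_only=recessive_only,
    )
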