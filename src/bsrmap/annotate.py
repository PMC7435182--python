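"""Candidate-gene extraction and SNP codon-effect annotation.

Given a fine-mapped interval, lists the overlapping gene models, classifies
a single-nucleotide substitution by its effect on the encoded protein
(synonymous / missense / nonsense / non-coding), and tests whether a SNP
co-segregates with a recessive phenotype across genotyped individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .types import GeneModel, GenomicInterval

__all__ = [
    "SnpEffect",
    "CosegregationResult",
    "genes_in_interval",
    "annotate_snp",
    "cosegregation_check",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SnpEffect:
    gene_id: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    effect_class: str  # synonymous | missense | nonsense | non_coding
    exon_index: int | None = None  # 1-based, transcription order
    cds_position: int | None = None  # 1-based position in the spliced CDS
    codon_number: int | None = None
    position_in_codon: int | None = None  # 1, 2 or 3
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None  # 3-letter code; "Ter" for stop
    alt_aa: str | None = None


@dataclass
class CosegregationResult:
    n_tested: int
    n_concordant: int
    cosegregates: bool
    discordant: list[str]


def genes_in_interval(
    genes: Sequence[GeneModel], interval: GenomicInterval
) -> list[GeneModel]:
    """Genes whose span overlaps the interval by at least one base,
    sorted by start."""
    hits = [g for g in genes if g.interval.overlaps(interval)]
    return sorted(hits, key=lambda g: g.gene_start)


def _fetch(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice of a chrom -> sequence mapping (dict or
    pyfaidx-like)."""
    seq = genome[chrom]
    return str(seq[start - 1 : end]).upper()


def _spliced_cds(gene: GeneModel, genome: Mapping[str, str]) -> str:
    parts = [_fetch(genome, gene.chrom, s, e) for s, e in gene.cds_segments]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def _aa3(codon: str) -> str:
    if codon in standard_dna_table.stop_codons:
        return "Ter"
    return seq3(str(Seq(codon).translate()))


def annotate_snp(
    gene: GeneModel,
    genome: Mapping[str, str],
    chrom: str,
    pos: int,
    ref_base: str,
    alt_base: str,
) -> SnpEffect:
    """Classify a substitution within a gene by its codon-level effect.

    The genomic reference base must match ``ref_base`` (fatal otherwise).
    Positions inside the gene but outside every CDS segment are classified
    ``non_coding``. Strand is respected: on minus-strand genes the CDS
    coordinate counts from the 3' genomic end and alleles are complemented.
    Translation uses the standard nuclear genetic code.
    """
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if chrom != gene.chrom or not (gene.gene_start <= pos <= gene.gene_end):
        raise ValueError(f"{chrom}:{pos} is outside gene {gene.gene_id}")
    genome_base = _fetch(genome, chrom, pos, pos)
    if genome_base != ref_base:
        raise ValueError(
            f"reference disagreement at {chrom}:{pos}: genome has "
            f"{genome_base}, caller says {ref_base}"
        )

    seg_idx = next(
        (i for i, (s, e) in enumerate(gene.cds_segments) if s <= pos <= e), None
    )
    if seg_idx is None:
        return SnpEffect(
            gene_id=gene.gene_id, chrom=chrom, pos=pos,
            ref_base=ref_base, alt_base=alt_base, effect_class="non_coding",
        )

    offset_in_seg = pos - gene.cds_segments[seg_idx][0]
    upstream = sum(e - s + 1 for s, e in gene.cds_segments[:seg_idx])
    cds0 = upstream + offset_in_seg  # 0-based on the + strand concatenation
    cds = _spliced_cds(gene, genome)
    n_segments = len(gene.cds_segments)
    if gene.strand == "-":
        cds0 = len(cds) - 1 - cds0
        exon_index = n_segments - seg_idx
        alt_cds_base = _COMPLEMENT[alt_base]
    else:
        exon_index = seg_idx + 1
        alt_cds_base = alt_base

    codon_number = cds0 // 3 + 1
    pos_in_codon = cds0 % 3 + 1
    codon_start = (codon_number - 1) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        # trailing partial codon of an out-of-frame model
        return SnpEffect(
            gene_id=gene.gene_id, chrom=chrom, pos=pos,
            ref_base=ref_base, alt_base=alt_base, effect_class="non_coding",
            exon_index=exon_index, cds_position=cds0 + 1,
        )
    alt_codon = ref_codon[: pos_in_codon - 1] + alt_cds_base + ref_codon[pos_in_codon:]
    ref_aa = _aa3(ref_codon)
    alt_aa = _aa3(alt_codon)
    if ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "Ter":
        effect = "nonsense"
    else:
        effect = "missense"
    return SnpEffect(
        gene_id=gene.gene_id,
        chrom=chrom,
        pos=pos,
        ref_base=ref_base,
        alt_base=alt_base,
        effect_class=effect,
        exon_index=exon_index,
        cds_position=cds0 + 1,
        codon_number=codon_number,
        position_in_codon=pos_in_codon,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )


def cosegregation_check(
    snp_genotypes: Mapping[str, str],
    phenotypes: Mapping[str, str],
) -> CosegregationResult:
    """Concordance of a SNP with a recessive phenotype.

    ``snp_genotypes`` maps individual -> {"mut", "het", "wt"} (homozygous
    mutant allele, heterozygous, homozygous wild allele); ``phenotypes``
    maps the same individuals -> {"mutant", "wildtype"}. Under the
    single-recessive model an individual is concordant iff
    (phenotype == mutant) <=> (genotype == mut).
    """
    if not snp_genotypes:
        raise ValueError("no individuals to test")
    if set(snp_genotypes) != set(phenotypes):
        raise ValueError("genotype and phenotype individuals differ")
    bad_g = set(snp_genotypes.values()) - {"mut", "het", "wt"}
    if bad_g:
        raise ValueError(f"unknown genotype labels: {sorted(bad_g)}")
    bad_p = set(phenotypes.values()) - {"mutant", "wildtype"}
    if bad_p:
        raise ValueError(f"unknown phenotype labels: {sorted(bad_p)}")
    discordant = [
        ind
        for ind in snp_genotypes
        if (phenotypes[ind] == "mutant") != (snp_genotypes[ind] == "mut")
    ]
    n = len(snp_genotypes)
    return CosegregationResult(
        n_tested=n,
        n_concordant=n - len(discordant),
        cosegregates=not discordant,
        discordant=sorted(discordant),
    )
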