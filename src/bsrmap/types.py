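"""Shared domain types for bulked-segregant mapping pipelines.

Coordinates are 1-based inclusive everywhere in the public API, matching
VCF/GFF3 convention. Half-open arithmetic, where used, is private to the
functions that need it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Genotype codes used in marker tables.
#: A = homozygous for the mutant-parent allele, H = heterozygous,
#: B = homozygous for the other parent's allele, U = missing/unknown.
GENOTYPE_CODES = ("A", "H", "B", "U")

#: Default mapping from common dialects of genotype symbols onto the
#: fixed {A, H, B, U} alphabet. Anything not covered maps to U.
DEFAULT_CODE_MAP = {
    "A": "A", "a": "A",
    "H": "H", "h": "H",
    "B": "B", "b": "B",
    "U": "U", "u": "U", "-": "U", ".": "U", "N": "U", "n": "U", "NA": "U",
}


@dataclass(frozen=True)
class PooledVariant:
    """One biallelic SNV with per-bulk read counts.

    The alt allele is, by convention of this pipeline, the allele carried by
    the mutant parent, but nothing downstream depends on that orientation:
    the Euclidean-distance statistic is symmetric in the two alleles.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    mut_ref_count: int
    mut_alt_count: int
    wt_ref_count: int
    wt_alt_count: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name in ("mut_ref_count", "mut_alt_count", "wt_ref_count", "wt_alt_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def mut_depth(self) -> int:
        return self.mut_ref_count + self.mut_alt_count

    @property
    def wt_depth(self) -> int:
        return self.wt_ref_count + self.wt_alt_count


@dataclass(frozen=True)
class GenomicInterval:
    """Chromosome plus 1-based inclusive start/end."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class MarkerGenotypeTable:
    """Genotype codes for individuals x markers.

    ``calls`` is an (n_individuals, n_markers) array of single-character
    codes from :data:`GENOTYPE_CODES`. ``recessive_only`` records whether
    the table holds only recessive-phenotype (mutant) individuals, the
    precondition for recombinant counting in fine mapping.
    """

    individuals: list[str]
    markers: list[str]
    marker_chroms: list[str]
    marker_pos: list[int]
    calls: np.ndarray
    recessive_only: bool = True

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U1")
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        if not (len(self.markers) == len(self.marker_chroms) == len(self.marker_pos)):
            raise ValueError("marker ids, chroms and positions must align")
        bad = set(np.unique(self.calls)) - set(GENOTYPE_CODES)
        if bad:
            raise ValueError(f"unknown genotype codes: {sorted(bad)}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def column(self, marker: str) -> np.ndarray:
        """Calls for one marker across all individuals."""
        j = self.markers.index(marker)
        return self.calls[:, j]


@dataclass
class GeneModel:
    """A protein-coding gene: bounds, strand and CDS segments.

    ``cds_segments`` are 1-based inclusive (start, end) pairs stored in
    ascending genomic order regardless of strand; transcription order on the
    minus strand is the reverse of storage order.
    """

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    cds_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.gene_end < self.gene_start:
            raise ValueError("gene_end < gene_start")
        self.cds_segments = sorted((int(s), int(e)) for s, e in self.cds_segments)
        prev_end = 0
        for s, e in self.cds_segments:
            if e < s:
                raise ValueError(f"CDS segment ({s}, {e}) reversed")
            if s <= prev_end:
                raise ValueError("CDS segments overlap")
            if s < self.gene_start or e > self.gene_end:
                raise ValueError(
                    f"CDS segment ({s}, {e}) outside gene bounds "
                    f"[{self.gene_start}, {self.gene_end}] of {self.gene_id}"
                )
            prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def frame_ok(self) -> bool:
        """True when the concatenated CDS length is a whole number of codons."""
        return self.cds_length % 3 == 0

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.gene_start, self.gene_end)


@dataclass(frozen=True)
class QpcrMeasurement:
    """Per-replicate qPCR cycle thresholds for a target and a reference gene."""

    sample_id: str
    group: str
    tissue: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")


def sort_variants(variants: Sequence[PooledVariant]) -> list[PooledVariant]:
    """Deterministic (chrom lexicographic, pos ascending) ordering."""
    return sorted(variants, key=lambda v: (v.chrom, v.pos))
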