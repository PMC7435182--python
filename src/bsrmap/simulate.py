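"""Synthetic F2 populations, phenotype-selected bulks and qPCR tables.

The generator emulates the study design of a recessive-mutant mapping
experiment: an F2 population segregating a single recessive causal locus,
two phenotype-selected bulks sequenced to moderate depth, marker genotypes
of the recessive homozygotes used for fine mapping, and replicate qPCR Ct
values — each with full ground truth retained, so downstream statistics can
be validated against known answers.

Model
-----
Each F2 individual inherits two gametes from independent F1 meioses. Per
chromosome a gamete carries Poisson(L/100) crossovers (L in cM) placed
uniformly — a no-interference (Haldane) process — and starts in either
parental phase with probability 1/2. The genetic map is linear in physical
position (constant cM/bp per chromosome). Phenotype is mutant iff both
gametes carry the mutant-parent allele at the causal locus.

Bulk sequencing draws per-SNV depths as Poisson(mean_depth) per pool and
alt-read counts as Binomial(depth, f') where f' is the pool allele
frequency perturbed symmetrically by the per-read error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import MarkerGenotypeTable, PooledVariant, QpcrMeasurement

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_f2",
    "simulate_bulks",
    "simulate_marker_genotypes",
    "simulate_qpcr",
]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults mirror a typical BSR-Seq design for a single recessive gene:
    bulks of 50 phenotyped individuals each, ~20x coverage per SNV per
    pool, and a few thousand informative SNVs per chromosome.
    """

    n_chromosomes: int = 3
    chrom_length_cm: float = 100.0
    chrom_length_bp: int = 30_000_000
    causal_chrom: str = "A01"
    causal_pos: int = 15_000_000
    n_f2: int = 600
    bulk_size: int = 50
    mean_depth: float = 20.0
    seq_error: float = 0.001
    n_snvs: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must be in [0, 0.5)")
        if self.chrom_length_cm < 0 or self.chrom_length_bp <= 0:
            raise ValueError("chromosome lengths must be positive")
        if self.causal_chrom not in self.chrom_names:
            raise ValueError(f"causal chromosome {self.causal_chrom!r} not simulated")
        if not 1 <= self.causal_pos <= self.chrom_length_bp:
            raise ValueError("causal position outside chromosome")

    @property
    def chrom_names(self) -> list[str]:
        return [f"A{i + 1:02d}" for i in range(self.n_chromosomes)]

    def bp_to_cm(self, pos_bp) -> np.ndarray:
        """Linear physical-to-genetic map (constant recombination rate)."""
        return np.asarray(pos_bp, dtype=float) * self.chrom_length_cm / self.chrom_length_bp


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent, reproducible streams per pipeline stage
    return np.random.default_rng([stream, seed])


@dataclass
class SimTruth:
    """Ground truth of a simulated F2: gametes, phenotypes, causal locus.

    Gametes are stored per chromosome as crossover breakpoints (cM) plus a
    starting phase; individual i owns gametes 2i and 2i+1. Allele 1 denotes
    the mutant-parent allele.
    """

    config: SimConfig
    breakpoints: dict[str, list[np.ndarray]]
    start_allele: dict[str, np.ndarray]
    phenotype_mutant: np.ndarray
    snv_truth: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_f2(self) -> int:
        return self.phenotype_mutant.size

    def gamete_alleles(self, chrom: str, pos_bp) -> np.ndarray:
        """(2*n_f2, n_positions) matrix of gamete alleles at given bp positions."""
        cm = self.config.bp_to_cm(pos_bp)
        starts = self.start_allele[chrom]
        out = np.empty((starts.size, cm.size), dtype=np.uint8)
        for g, bps in enumerate(self.breakpoints[chrom]):
            n_cross = np.searchsorted(bps, cm, side="right")
            out[g] = (starts[g] + n_cross) % 2
        return out

    def dosage(self, chrom: str, pos_bp) -> np.ndarray:
        """(n_f2, n_positions) count of mutant-parent alleles per individual."""
        alleles = self.gamete_alleles(chrom, pos_bp)
        return alleles[0::2].astype(np.int8) + alleles[1::2]


def simulate_f2(config: SimConfig) -> SimTruth:
    """Simulate an F2 population segregating one recessive causal locus.

    Reproducible for a given ``config.seed``; the expected mutant fraction
    is 1/4 (single recessive gene).
    """
    rng = _rng(config.seed, 0)
    n_gametes = 2 * config.n_f2
    length_cm = config.chrom_length_cm
    breakpoints: dict[str, list[np.ndarray]] = {}
    start_allele: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names:
        counts = rng.poisson(length_cm / 100.0, size=n_gametes)
        breakpoints[chrom] = [
            np.sort(rng.uniform(0.0, length_cm, size=k)) for k in counts
        ]
        start_allele[chrom] = rng.integers(0, 2, size=n_gametes, dtype=np.uint8)
    truth = SimTruth(
        config=config,
        breakpoints=breakpoints,
        start_allele=start_allele,
        phenotype_mutant=np.zeros(config.n_f2, dtype=bool),
    )
    dosage = truth.dosage(config.causal_chrom, [config.causal_pos])[:, 0]
    truth.phenotype_mutant = dosage == 2
    return truth


def simulate_bulks(truth: SimTruth, config: SimConfig | None = None) -> list[PooledVariant]:
    """Sequence two phenotype-selected bulks over random SNV positions.

    The mutant bulk holds ``bulk_size`` recessive-phenotype individuals, the
    wild bulk ``bulk_size`` of the rest. At each SNV the pool allele
    frequency is the mean of the 2*bulk_size gamete alleles; the observed
    counts add Poisson depth and binomial sampling with symmetric
    sequencing error. True pool frequencies are stored in
    ``truth.snv_truth[chrom]`` as (pos, f_mut, f_wt) rows.
    """
    config = config or truth.config
    rng = _rng(config.seed, 1)
    mutant_idx = np.flatnonzero(truth.phenotype_mutant)
    wild_idx = np.flatnonzero(~truth.phenotype_mutant)
    if mutant_idx.size < config.bulk_size:
        raise ValueError(
            f"need {config.bulk_size} mutant individuals for the bulk, "
            f"have {mutant_idx.size}; increase n_f2"
        )
    if wild_idx.size < config.bulk_size:
        raise ValueError(
            f"need {config.bulk_size} wild-type individuals, have {wild_idx.size}"
        )
    mut_bulk = mutant_idx[: config.bulk_size]
    wt_bulk = wild_idx[: config.bulk_size]
    gamete_rows = lambda idx: np.concatenate([2 * idx, 2 * idx + 1])  # noqa: E731

    variants: list[PooledVariant] = []
    e = config.seq_error
    for chrom in config.chrom_names:
        pos = np.sort(
            rng.choice(config.chrom_length_bp, size=config.n_snvs, replace=False) + 1
        )
        alleles = truth.gamete_alleles(chrom, pos)
        f_mut = alleles[gamete_rows(mut_bulk)].mean(axis=0)
        f_wt = alleles[gamete_rows(wt_bulk)].mean(axis=0)
        truth.snv_truth[chrom] = np.column_stack([pos, f_mut, f_wt])
        for pool_f, prefix in ((f_mut, "mut"), (f_wt, "wt")):
            depth = rng.poisson(config.mean_depth, size=pos.size)
            obs_f = pool_f * (1 - e) + (1 - pool_f) * e
            alt = rng.binomial(depth, obs_f)
            if prefix == "mut":
                mut_depth, mut_alt = depth, alt
            else:
                wt_depth, wt_alt = depth, alt
        for i in range(pos.size):
            variants.append(
                PooledVariant(
                    chrom=chrom,
                    pos=int(pos[i]),
                    ref_allele="C",
                    alt_allele="T",
                    mut_ref_count=int(mut_depth[i] - mut_alt[i]),
                    mut_alt_count=int(mut_alt[i]),
                    wt_ref_count=int(wt_depth[i] - wt_alt[i]),
                    wt_alt_count=int(wt_alt[i]),
                )
            )
    return variants


def simulate_marker_genotypes(
    truth: SimTruth,
    marker_positions: list[tuple[str, str, int]],
    restrict: str = "recessive_only",
) -> MarkerGenotypeTable:
    """Read marker genotypes off the stored gametes (no added noise).

    ``marker_positions`` is a list of (marker_id, chrom, pos_bp). With
    ``restrict='recessive_only'`` only mutant-phenotype individuals are
    kept — the standard fine-mapping population for a recessive trait.
    """
    if restrict not in ("recessive_only", "all"):
        raise ValueError("restrict must be 'recessive_only' or 'all'")
    config = truth.config
    for _, chrom, pos in marker_positions:
        if chrom not in config.chrom_names:
            raise ValueError(f"marker chromosome {chrom!r} not simulated")
        if not 1 <= pos <= config.chrom_length_bp:
            raise ValueError(f"marker position {pos} outside chromosome {chrom}")
    keep = (
        np.flatnonzero(truth.phenotype_mutant)
        if restrict == "recessive_only"
        else np.arange(truth.n_f2)
    )
    code = np.array(["B", "H", "A"])  # dosage 0/1/2 of the mutant-parent allele
    columns = []
    for _, chrom, pos in marker_positions:
        dosage = truth.dosage(chrom, [pos])[keep, 0]
        columns.append(code[dosage])
    return MarkerGenotypeTable(
        individuals=[f"F2_{i:05d}" for i in keep],
        markers=[m for m, _, _ in marker_positions],
        marker_chroms=[c for _, c, _ in marker_positions],
        marker_pos=[p for _, _, p in marker_positions],
        calls=np.column_stack(columns),
        recessive_only=(restrict == "recessive_only"),
    )


def simulate_qpcr(
    n_per_group: int = 3,
    fold_change: float = 1.0,
    sd_ct: float = 0.2,
    seed: int = 0,
    tissue: str = "leaf",
    base_ct_target: float = 24.0,
    base_ct_reference: float = 18.0,
) -> list[QpcrMeasurement]:
    """Replicate Ct values for a mutant vs wild-type qPCR comparison.

    The mutant group's target Ct is shifted by -log2(fold_change) relative
    to wild type (higher expression = fewer cycles); reference Ct is the
    same constant in both groups. Gaussian noise with sd ``sd_ct`` is added
    to every Ct independently.
    """
    if fold_change <= 0:
        raise ValueError("fold_change must be > 0")
    if n_per_group < 2:
        raise ValueError("need at least 2 replicates per group")
    rng = _rng(seed, 3)
    shift = -np.log2(fold_change)
    out: list[QpcrMeasurement] = []
    for group, delta in (("wildtype", 0.0), ("mutant", shift)):
        for i in range(n_per_group):
            out.append(
                QpcrMeasurement(
                    sample_id=f"{group}_{i + 1}",
                    group=group,
                    tissue=tissue,
                    ct_target=base_ct_target + delta + rng.normal(0.0, sd_ct),
                    ct_reference=base_ct_reference + rng.normal(0.0, sd_ct),
                )
            )
    return out
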