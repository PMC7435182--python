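"""Mendelian segregation tests and recombinant-based fine mapping.

Segregation tests are Pearson chi-squared goodness-of-fit tests against an
expected ratio (3:1 for an F2 under one recessive gene, 1:1 for a backcross),
judged at the 0.05 critical value (3.84 for one degree of freedom).

Fine mapping counts recombinant gametes at each marker across the
recessive-homozygous F2 individuals: because every such individual carries
two mutant gametes at the trait locus, a heterozygous marker call reveals
one recombinant gamete and a wild-homozygous call two. Recombination
frequency r = recombinants / (2N) is converted to map distance with
Kosambi's function

    cM = 25 * ln((1 + 2r) / (1 - 2r)),

which approaches 100*r for tightly linked markers. Markers are partitioned
onto the two sides of the trait locus by the identity of their recombinant
individuals — markers sharing recombinants sit on the same side, markers
with disjoint recombinant sets on opposite sides — and the interval between
the closest flanking markers with recombinants is the fine-mapped region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .types import GenomicInterval, MarkerGenotypeTable

logger = logging.getLogger("bsrmap")

__all__ = [
    "SegregationTest",
    "chi_square_segregation",
    "segregation_ratio",
    "format_segregation_ratio",
    "count_recombinant_gametes",
    "recombination_frequency",
    "kosambi_cM",
    "MarkerMapResult",
    "FineMapResult",
    "assign_sides_and_interval",
    "physical_span",
]


@dataclass
class SegregationTest:
    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    expected: tuple[float, ...]
    chi2: float
    p_value: float
    df: int
    critical_value: float
    conclusion: str  # "fits" or "rejects"


def chi_square_segregation(
    observed: Sequence[int],
    ratio: Sequence[float],
    alpha: float = 0.05,
    yates: bool = False,
) -> SegregationTest:
    """Pearson chi-squared test of observed class counts against a ratio.

    ``yates`` applies the continuity correction (|obs-exp| reduced by 0.5);
    the default is the uncorrected Pearson statistic.
    """
    observed = tuple(int(x) for x in observed)
    ratio = tuple(float(x) for x in ratio)
    if len(observed) < 2 or len(observed) != len(ratio):
        raise ValueError("need >= 2 classes and matching ratio length")
    total = sum(observed)
    if total <= 0:
        raise ValueError("total count must be positive")
    props = np.asarray(ratio) / sum(ratio)
    expected = props * total
    if np.any(expected == 0):
        raise ValueError("expected count of zero in some class")
    dev = np.abs(np.asarray(observed) - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float(np.sum(dev**2 / expected))
    df = len(observed) - 1
    p = float(stats.chi2.sf(chi2, df))
    crit = float(stats.chi2.ppf(1 - alpha, df))
    return SegregationTest(
        observed=observed,
        expected_ratio=ratio,
        expected=tuple(expected),
        chi2=chi2,
        p_value=p,
        df=df,
        critical_value=crit,
        conclusion="fits" if chi2 < crit else "rejects",
    )


def segregation_ratio(observed: Sequence[int]) -> float:
    """Ratio of the first class to the second, as the x of "x:1", 3 decimals.

    A zero second class yields inf (formatted as "all:0")."""
    a, b = observed
    if b == 0:
        return math.inf
    return round(a / b, 3)


def format_segregation_ratio(x: float) -> str:
    return "all:0" if math.isinf(x) else f"{x:.3f}:1"


def count_recombinant_gametes(calls: Sequence[str]) -> tuple[int, int]:
    """Recombinant gametes revealed by one marker among recessive homozygotes.

    A = 0 recombinant gametes, H = 1, B = 2; U (missing) is excluded from
    the scored count. Returns (recombinant_gametes, n_scored individuals).
    """
    weight = {"A": 0, "H": 1, "B": 2}
    rec = 0
    n = 0
    for c in calls:
        if c == "U":
            continue
        try:
            rec += weight[c]
        except KeyError:
            raise ValueError(f"unknown genotype code {c!r}") from None
        n += 1
    return rec, n


def recombination_frequency(recombinant_gametes: int, n_scored: int) -> float:
    """r = recombinant gametes / (2 * scored individuals)."""
    if n_scored <= 0:
        raise ValueError("n_scored must be positive")
    if not 0 <= recombinant_gametes <= 2 * n_scored:
        raise ValueError("recombinant gametes outside [0, 2N]")
    r = recombinant_gametes / (2 * n_scored)
    if r > 0.5:
        logger.warning("r = %.4f > 0.5: marker behaves as unlinked", r)
    return r


def kosambi_cM(r: float) -> float:
    """Kosambi map distance in centimorgans; defined for 0 <= r < 0.5."""
    if r < 0:
        raise ValueError("recombination frequency cannot be negative")
    if r >= 0.5:
        raise ValueError("r >= 0.5 maps to infinite Kosambi distance")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


@dataclass
class MarkerMapResult:
    marker: str
    chrom: str
    pos: int
    recombinant_gametes: int
    recombinant_individuals: int
    n_scored: int
    r: float
    cM: float
    side: str  # "left", "right" or "cosegregating"


@dataclass
class FineMapResult:
    """Fine-mapping outcome: per-marker statistics plus the flanked interval.

    ``status`` is "resolved" when two flanking markers exist, "unresolved"
    when every marker co-segregates. ``conflicts`` lists individuals
    recombinant on both sides of the locus — double crossovers, or
    genotyping errors masquerading as them."""

    markers: list[MarkerMapResult]
    interval: GenomicInterval | None
    left_marker: str | None
    right_marker: str | None
    cosegregating_markers: list[str]
    status: str
    conflicts: list[str] = field(default_factory=list)


def _recombinant_sets(table: MarkerGenotypeTable) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for j, marker in enumerate(table.markers):
        col = table.calls[:, j]
        rec = {
            table.individuals[i]
            for i in range(table.n_individuals)
            if col[i] in ("H", "B")
        }
        sets[marker] = rec
    return sets


def assign_sides_and_interval(
    table: MarkerGenotypeTable, force: bool = False
) -> FineMapResult:
    """Partition markers around the trait locus and return the flanked interval.

    Requires a recessive-homozygote-only table (the recombinant weighting
    A=0/H=1/B=2 is meaningless otherwise); pass ``force=True`` to override.
    Markers with zero recombinants co-segregate with the trait; the rest are
    split into the two sides at the position that minimises sharing of
    recombinant individuals across the split, and the interval runs between
    the innermost marker of each side.
    """
    if not table.recessive_only and not force:
        raise ValueError(
            "fine mapping requires recessive-phenotype individuals only "
            "(use force=True to override)"
        )
    if any(c != table.marker_chroms[0] for c in table.marker_chroms):
        raise ValueError("fine-mapping markers must lie on one chromosome")
    chrom = table.marker_chroms[0]
    rec_sets = _recombinant_sets(table)

    order = np.argsort(table.marker_pos)
    results: dict[str, MarkerMapResult] = {}
    for j in order:
        marker = table.markers[j]
        rec, n = count_recombinant_gametes(table.calls[:, j])
        r = recombination_frequency(rec, n) if n else 0.0
        results[marker] = MarkerMapResult(
            marker=marker,
            chrom=chrom,
            pos=table.marker_pos[j],
            recombinant_gametes=rec,
            recombinant_individuals=len(rec_sets[marker]),
            n_scored=n,
            r=r,
            cM=kosambi_cM(r) if r < 0.5 else math.inf,
            side="cosegregating",
        )

    informative = [table.markers[j] for j in order if results[table.markers[j]].recombinant_gametes > 0]
    coseg = [m for m in (table.markers[j] for j in order) if m not in informative]

    if not informative:
        return FineMapResult(
            markers=[results[table.markers[j]] for j in order],
            interval=None,
            left_marker=None,
            right_marker=None,
            cosegregating_markers=coseg,
            status="unresolved",
        )
    if len(informative) == 1:
        raise ValueError(
            f"cannot flank the locus: only one marker ({informative[0]}) "
            "shows recombinants"
        )

    # split the informative markers (already in bp order) at the point that
    # minimises recombinant individuals shared between the two sides
    best_split, best_score = None, None
    for s in range(1, len(informative)):
        left_union = set().union(*(rec_sets[m] for m in informative[:s]))
        right_union = set().union(*(rec_sets[m] for m in informative[s:]))
        score = len(left_union & right_union)
        if best_score is None or score < best_score:
            best_split, best_score = s, score
    left = informative[:best_split]
    right = informative[best_split:]
    conflicts = sorted(
        set().union(*(rec_sets[m] for m in left))
        & set().union(*(rec_sets[m] for m in right))
    )
    if conflicts:
        logger.warning(
            "%d individual(s) are recombinant on both sides of the locus "
            "(double crossover or genotyping conflict): %s",
            len(conflicts), ", ".join(conflicts),
        )
    for m in left:
        results[m].side = "left"
    for m in right:
        results[m].side = "right"

    left_marker = left[-1]  # innermost on each side
    right_marker = right[0]
    interval = GenomicInterval(
        chrom, results[left_marker].pos, results[right_marker].pos
    )
    for m in coseg:
        if not interval.contains(chrom, results[m].pos):
            logger.warning(
                "co-segregating marker %s at %s:%d lies outside the flanked "
                "interval %d-%d", m, chrom, results[m].pos, interval.start, interval.end
            )
    return FineMapResult(
        markers=[results[table.markers[j]] for j in order],
        interval=interval,
        left_marker=left_marker,
        right_marker=right_marker,
        cosegregating_markers=coseg,
        status="resolved",
        conflicts=conflicts,
    )


def physical_span(interval: GenomicInterval) -> float:
    """Interval length in kb, 2 decimals (1-based inclusive arithmetic)."""
    return round(interval.length_bp / 1000.0, 2)
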