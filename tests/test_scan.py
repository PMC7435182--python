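import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsrmap import (
    PooledVariant,
    SimConfig,
    allele_frequencies,
    call_regions,
    depth_filter,
    ed_statistic,
    power_transform,
    scan,
    simulate_bulks,
    simulate_f2,
    top_quantile_threshold,
)

SQRT2 = math.sqrt(2.0)


def pv(chrom="A01", pos=1, mut=(5, 5), wt=(5, 5)):
    return PooledVariant(chrom, pos, "C", "T", mut[0], mut[1], wt[0], wt[1])


class TestDepthFilter:
    def test_boundary_is_strict(self):
        kept = depth_filter([pv(mut=(2, 2), wt=(2, 2))], min_depth=3)  # depth 4 each
        assert len(kept) == 1
        kept = depth_filter([pv(mut=(1, 2), wt=(5, 5))], min_depth=3)  # mut depth 3
        assert kept == []

    def test_min_depth_zero_keeps_covered_variants(self):
        variants = [pv(pos=i + 1, mut=(i, 1), wt=(1, i)) for i in range(100)]
        assert depth_filter(variants, min_depth=0) == variants


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "mut, wt, expected",
        [((0, 10), (5, 5), (1.0, 0.5)), ((10, 0), (5, 5), (0.0, 0.5)),
         ((3, 7), (5, 5), (0.7, 0.5))],
    )
    def test_arithmetic(self, mut, wt, expected):
        assert allele_frequencies(pv(mut=mut, wt=wt)) == pytest.approx(expected)

    def test_zero_depth_flagged(self):
        with pytest.raises(ZeroDivisionError):
            allele_frequencies(pv(mut=(0, 0), wt=(5, 5)))


class TestEdStatistic:
    @pytest.mark.parametrize(
        "f_mut, f_wt, expected",
        [(0.5, 0.5, 0.0), (1.0, 0.0, SQRT2), (1.0, 0.5, 0.70711)],
    )
    def test_examples(self, f_mut, f_wt, expected):
        assert ed_statistic(f_mut, f_wt) == pytest.approx(expected, abs=1e-5)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_closed_form_and_bounds(self, f_mut, f_wt):
        """Two-term formula equals sqrt(2)|df|; 0 <= ED <= sqrt(2)."""
        ed = ed_statistic(f_mut, f_wt)
        assert ed == pytest.approx(SQRT2 * abs(f_mut - f_wt), abs=1e-12)
        assert 0 <= ed <= SQRT2 + 1e-12

    def test_frequency_out_of_range(self):
        with pytest.raises(ValueError):
            ed_statistic(1.2, 0.5)


class TestPowerTransform:
    @pytest.mark.parametrize(
        "ed, k, expected", [(0.0, 5, 0.0), (1.0, 5, 1.0), (SQRT2, 5, 2**2.5)]
    )
    def test_examples(self, ed, k, expected):
        assert power_transform(ed, k) == pytest.approx(expected, abs=1e-9)


class TestThreshold:
    def test_top_one_percent_of_distinct_values(self):
        """Brute-force oracle: selection by the threshold equals taking the
        ceil(q*n) largest after a full sort."""
        rng = np.random.default_rng(42)
        values = rng.permutation(np.linspace(0.001, 1.0, 1000))
        t = top_quantile_threshold(values, q=0.01)
        selected = np.sort(values[values >= t])
        expected = np.sort(values)[-10:]
        assert np.array_equal(selected, expected)

    def test_all_equal_all_selected(self):
        values = np.full(500, 0.3)
        t = top_quantile_threshold(values, q=0.01)
        assert (values >= t).all()

    def test_single_value(self):
        assert top_quantile_threshold([0.7], q=0.01) == 0.7

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            top_quantile_threshold([], q=0.01)

    @given(
        st.lists(
            st.one_of(st.just(0.0), st.floats(1e-6, SQRT2)),
            min_size=5,
            max_size=200,
        )
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_thresholding_commutes_with_power(self, eds):
        """Selecting top q by ED equals selecting top q by ED^5 (strictly
        increasing transform). EDs are either 0 or >= 1e-6, the resolution
        attainable from read-count ratios, so the 5th power cannot underflow."""
        eds = np.asarray(eds)
        by_ed = set(np.flatnonzero(eds >= top_quantile_threshold(eds, 0.05)))
        ed5 = power_transform(eds, 5)
        by_ed5 = set(np.flatnonzero(ed5 >= top_quantile_threshold(ed5, 0.05)))
        assert by_ed == by_ed5


class TestCallRegions:
    def test_close_positions_merge(self):
        regions = call_regions(
            [("A01", 1_000_000), ("A01", 1_200_000), ("A01", 1_500_000)],
            max_gap_bp=2_000_000, min_snv=1,
        )
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1_000_000, 1_500_000)

    def test_large_gap_splits(self):
        regions = call_regions(
            [("A01", 1_000_000), ("A01", 9_100_000)], max_gap_bp=2_000_000, min_snv=1
        )
        assert len(regions) == 2

    def test_min_snv_drops_small_clusters(self):
        regions = call_regions(
            [("A01", 1_000_000), ("A01", 1_100_000), ("A02", 5_000_000)],
            max_gap_bp=2_000_000, min_snv=2,
        )
        assert len(regions) == 1
        assert regions[0].chrom == "A01"

    def test_empty_selection(self):
        assert call_regions([], 2_000_000, 5) == []

    def test_matches_brute_force_clustering(self):
        """O(n^2) oracle: two positions share a region iff a chain of
        selected positions with gaps <= max_gap connects them."""
        rng = np.random.default_rng(7)
        positions = sorted(rng.choice(10_000_000, 60, replace=False) + 1)
        max_gap = 400_000
        regions = call_regions([("A01", int(p)) for p in positions], max_gap, 1)
        # brute force: split wherever the gap exceeds max_gap
        clusters, current = [], [positions[0]]
        for p in positions[1:]:
            if p - current[-1] > max_gap:
                clusters.append(current)
                current = []
            current.append(p)
        clusters.append(current)
        assert [(r.start, r.end) for r in regions] == [(c[0], c[-1]) for c in clusters]


class TestScan:
    def test_order_invariance(self):
        cfg = SimConfig(seed=31, n_f2=300, n_snvs=300)
        variants = simulate_bulks(simulate_f2(cfg), cfg)
        rng = np.random.default_rng(0)
        shuffled = list(variants)
        rng.shuffle(shuffled)
        r1, r2 = scan(variants), scan(shuffled)
        assert r1.threshold == r2.threshold
        assert r1.regions == r2.regions
        assert r1.records.equals(r2.records)

    def test_recovers_causal_locus_single_replicate(self):
        cfg = SimConfig(seed=33)
        variants = simulate_bulks(simulate_f2(cfg), cfg)
        result = scan(variants)
        assert any(r.contains(cfg.causal_chrom, cfg.causal_pos) for r in result.regions)
        # threshold bound and tie rule
        n_selected = int(result.records["selected"].sum())
        assert n_selected >= math.ceil(0.01 * len(result.records))
        assert result.records["ed"].max() <= SQRT2 + 1e-12

    def test_null_data_signal_is_scattered(self):
        """Without a causal locus the top-1% SNVs spread evenly over the
        genome: no chromosome concentrates the selection, and no called
        region concentrates more than a modest share of the selected SNVs —
        in contrast to the causal case, where the causal region alone
        captures most of them."""
        rng = np.random.default_rng(55)
        max_chrom_share = []
        max_region_share = []
        for _ in range(25):
            variants = []
            for chrom in ("A01", "A02", "A03"):
                pos = np.sort(rng.choice(30_000_000, 2000, replace=False) + 1)
                depth_m = rng.poisson(20, 2000)
                depth_w = rng.poisson(20, 2000)
                alt_m = rng.binomial(depth_m, 0.5)
                alt_w = rng.binomial(depth_w, 0.5)
                variants += [
                    PooledVariant(chrom, int(p), "C", "T",
                                  int(dm - am), int(am), int(dw - aw), int(aw))
                    for p, dm, am, dw, aw in zip(pos, depth_m, alt_m, depth_w, alt_w)
                ]
            result = scan(variants)
            sel = result.selected
            max_chrom_share.append(sel["chrom"].value_counts().max() / len(sel))
            in_regions = [
                ((sel["chrom"] == r.chrom) & sel["pos"].between(r.start, r.end)).sum()
                for r in result.regions
            ]
            max_region_share.append(max(in_regions, default=0) / len(sel))
        assert np.mean(max_chrom_share) < 0.5
        assert np.mean(max_region_share) < 0.5

    def test_causal_region_concentrates_selected_snvs(self):
        """Counterpart of the null test: with a causal locus, the region
        containing it captures the majority of the selected SNVs."""
        cfg = SimConfig(seed=57)
        variants = simulate_bulks(simulate_f2(cfg), cfg)
        result = scan(variants)
        sel = result.selected
        causal_region = next(
            r for r in result.regions if r.contains(cfg.causal_chrom, cfg.causal_pos)
        )
        inside = (
            (sel["chrom"] == causal_region.chrom)
            & sel["pos"].between(causal_region.start, causal_region.end)
        ).sum()
        assert inside / len(sel) > 0.5
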