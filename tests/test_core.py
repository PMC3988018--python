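import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cmtpeaks.core import (
    CMTParams,
    GapWindowError,
    ScanStats,
    between_class_variance,
    between_class_variance_sweep,
    find_division_point,
    gap_skip,
    scan_chromosome,
)
from cmtpeaks.io_formats import CoverageHistogram

from _oracles import division_point_oracle, sigma_b2_direct


def hist(counts, origin=0, chrom="chr1"):
    return CoverageHistogram(chrom, origin, np.asarray(counts, dtype=np.int64))


class TestBetweenClassVariance:
    def test_single_spike_gives_zero(self):
        counts = np.zeros(30, dtype=int)
        counts[7] = 12
        for t in (0, 6, 7, 15, 28):
            assert between_class_variance(counts, t) == 0.0

    def test_two_equal_spikes_closed_form(self):
        """Two equal point masses d apart: sigma_B^2 = 1/4 * d^2 when split
        between them."""
        counts = np.zeros(30, dtype=int)
        counts[10] = counts[20] = 5
        assert between_class_variance(counts, 14) == pytest.approx(25.0)

    def test_symmetric_block_pair_plateau(self):
        counts = np.array([4, 0, 0, 4])
        vals = [between_class_variance(counts, t) for t in range(3)]
        assert vals == pytest.approx([2.25, 2.25, 2.25])

    def test_all_zero_window_is_an_error(self):
        with pytest.raises(GapWindowError):
            between_class_variance(np.zeros(10, dtype=int), 3)

    def test_split_index_bounds(self):
        with pytest.raises(ValueError):
            between_class_variance(np.array([1, 2, 3]), 2)  # t must be < n-1

    @given(st.integers(0, 2**32 - 1), st.integers(10, 400))
    def test_decomposition_identity_and_closed_form(self, seed, size):
        """w1*mu1 + w2*mu2 == muT and sigma_B^2 == w1*w2*(mu1-mu2)^2 at every
        split of a random window (1e-9 relative tolerance)."""
        rng = np.random.default_rng(seed)
        counts = rng.poisson(3.0, size=size) + rng.integers(0, 2, size=size)
        if counts.sum() == 0:
            counts[size // 2] = 5
        p = counts / counts.sum()
        idx = np.arange(size, dtype=float)
        mu_t = float(idx @ p)
        for t in range(0, size - 1, max(1, size // 17)):
            w1 = p[: t + 1].sum()
            w2 = 1.0 - w1
            if w1 <= 0 or w2 <= 0:
                continue
            mu1 = float(idx[: t + 1] @ p[: t + 1]) / w1
            mu2 = float(idx[t + 1 :] @ p[t + 1 :]) / w2
            assert w1 * mu1 + w2 * mu2 == pytest.approx(mu_t, rel=1e-9)
            assert between_class_variance(counts, t) == pytest.approx(
                w1 * w2 * (mu1 - mu2) ** 2, rel=1e-9, abs=1e-12
            )

    @given(st.integers(0, 2**32 - 1), st.integers(5, 300))
    def test_sweep_matches_per_split_recomputation(self, seed, size):
        """The O(1)-per-step running-sum sweep agrees with direct summation
        at every split (incremental-update correctness)."""
        rng = np.random.default_rng(seed)
        counts = rng.poisson(2.0, size=size)
        counts[int(rng.integers(size))] += 10
        sweep = between_class_variance_sweep(counts)
        direct = np.array([sigma_b2_direct(counts, t) for t in range(size - 1)])
        np.testing.assert_allclose(sweep, direct, rtol=1e-9, atol=1e-12)


class TestFindDivisionPoint:
    def params(self, min_region=10, max_region=200, thr=1.0):
        return CMTParams(
            fragment_length=100, min_region=min_region, max_region=max_region,
            cutoff=1.0, min_supported_reads=thr, k_fold=2.0,
        )

    @staticmethod
    def triangle(width, height):
        up = np.linspace(1, height, width // 2)
        return np.concatenate([up, up[::-1]]).astype(int)

    def test_valley_between_two_equal_peaks(self):
        tri = self.triangle(40, 20)
        counts = np.concatenate([tri, np.zeros(60, dtype=int), tri])
        h = hist(counts)
        division = find_division_point(h, 0, self.params())
        # centre of the zero valley [40, 100)
        assert 60 <= division <= 80

    def test_matches_oracle_on_isolated_peak(self):
        counts = np.zeros(200, dtype=int)
        counts[50:90] = self.triangle(40, 30)
        h = hist(counts)
        p = self.params(min_region=10, max_region=200)
        division = find_division_point(h, 0, p)
        t_star = division_point_oracle(counts, t_lo=9, t_hi=199)
        assert division == t_star + 1

    def test_min_region_constraint_binds(self):
        """A valley closer than min_region cannot take the division."""
        counts = np.concatenate(
            [np.full(5, 30), np.zeros(10, dtype=int), np.full(185, 8)]
        )
        h = hist(counts)
        division = find_division_point(h, 0, self.params(min_region=50))
        assert division >= 50

    def test_unsupported_window_signals_gap(self):
        h = hist(np.ones(100, dtype=int))
        with pytest.raises(GapWindowError):
            find_division_point(h, 0, self.params(thr=5.0))

    def test_window_shrinks_at_chromosome_end(self):
        counts = np.zeros(120, dtype=int)
        counts[40:80] = 20
        h = hist(counts)
        division = find_division_point(h, 0, self.params(min_region=10, max_region=500))
        assert 10 <= division <= 119

    def test_counts_sigma_evaluations(self):
        counts = np.zeros(200, dtype=int)
        counts[100:110] = 20
        stats = ScanStats()
        find_division_point(hist(counts), 0, self.params(), stats)
        # admissible splits: t in [min_region-1, max_region-1) = [9, 199)
        assert stats.sigma_evaluations == 190
        assert stats.windows == 1


class TestGapSkip:
    def params(self, max_region=100, thr=5.0):
        return CMTParams(
            fragment_length=100, min_region=10, max_region=max_region,
            min_supported_reads=thr,
        )

    def test_all_zero_returns_end_sentinel(self):
        h = hist(np.zeros(500, dtype=int))
        assert gap_skip(h, 0, self.params()) == h.end

    def test_far_signal_window_reaches_it(self):
        counts = np.zeros(1_000_000, dtype=int)
        counts[900_000] = 10
        h = hist(counts)
        p = self.params(max_region=100)
        pos = gap_skip(h, 0, p)
        assert pos <= 900_000
        assert h.slice(pos, pos + p.max_region).max() >= p.min_supported_reads
        # smallest such position: one bp earlier misses the signal
        assert h.slice(pos - 1, pos - 1 + p.max_region).max() < p.min_supported_reads

    def test_inside_signal_is_identity(self):
        counts = np.zeros(300, dtype=int)
        counts[100:200] = 10
        h = hist(counts)
        assert gap_skip(h, 150, self.params()) == 150

    def test_respects_histogram_origin(self):
        counts = np.zeros(500, dtype=int)
        counts[400] = 9
        h = hist(counts, origin=10_000)
        pos = gap_skip(h, 10_000, self.params(max_region=50))
        assert pos == 10_000 + 400 - 49


class TestScanChromosome:
    def params(self, **kw):
        defaults = dict(
            fragment_length=100, min_region=50, max_region=1000,
            cutoff=1.0, min_supported_reads=5.0, k_fold=2.0,
        )
        defaults.update(kw)
        return CMTParams(**defaults)

    def test_flat_zero_histogram_gives_nothing(self):
        assert scan_chromosome(hist(np.zeros(5000, dtype=int)), self.params()) == []

    def test_empty_histogram_gives_nothing(self):
        assert scan_chromosome(hist(np.zeros(0, dtype=int)), self.params()) == []

    def test_single_block_yields_one_covering_candidate(self):
        """A lone enriched block over flat background ends up inside exactly
        one candidate region."""
        counts = np.ones(5000, dtype=int)
        counts[2000:2200] = 10
        regions = scan_chromosome(hist(counts), self.params())
        covering = [r for r in regions if r.start <= 2000 and r.end >= 2200]
        assert len(covering) == 1
        assert covering[0].height == 10
        assert 2000 <= covering[0].summit < 2200

    def test_zero_background_block_is_still_fully_covered(self):
        """Without any background mass the division criterion may cut through
        an isolated block, but all of its supported signal stays inside
        candidates."""
        counts = np.zeros(5000, dtype=int)
        counts[2000:2200] = 10
        p = self.params()
        regions = scan_chromosome(hist(counts), p)
        covered = np.zeros(5000, dtype=bool)
        for r in regions:
            covered[r.start : r.end] = True
        assert covered[2000:2200].all()

    def test_two_blocks_split_in_the_gap(self):
        counts = np.ones(6000, dtype=int)
        counts[1000:1200] = 10
        counts[1800:2000] = 10
        regions = scan_chromosome(hist(counts), self.params())
        (c1,) = [r for r in regions if r.start <= 1000 and r.end >= 1200]
        (c2,) = [r for r in regions if r.start <= 1800 and r.end >= 2000]
        assert c1.end <= c2.start
        assert 1200 <= c1.end <= 1800  # division falls in the inter-block gap

    def test_candidates_sorted_and_non_overlapping(self, rng):
        counts = rng.poisson(1.0, size=50_000)
        for centre in (5_000, 20_000, 33_000, 41_000):
            counts[centre : centre + 150] += 20
        regions = scan_chromosome(hist(counts), self.params())
        for a, b in zip(regions, regions[1:]):
            assert a.end <= b.start

    def test_completeness_every_supported_bin_is_covered(self, rng):
        """Every bin at or above min_supported_reads lies inside a candidate."""
        counts = rng.poisson(1.0, size=30_000)
        for centre in (4_000, 11_111, 22_222):
            counts[centre : centre + 80] += 25
        p = self.params()
        h = hist(counts)
        regions = scan_chromosome(h, p)
        supported = np.flatnonzero(counts >= p.min_supported_reads)
        covered = np.zeros(len(counts), dtype=bool)
        for r in regions:
            covered[r.start - h.origin : r.end - h.origin] = True
        assert covered[supported].all()

    def test_emitted_candidates_carry_supported_heights(self, rng):
        counts = rng.poisson(1.0, size=20_000)
        counts[9_000:9_100] += 30
        p = self.params()
        for r in scan_chromosome(hist(counts), p):
            assert r.height >= p.min_supported_reads

    def test_broad_domain_tiles_into_max_region_pieces(self):
        """Signal wider than max_region is tiled by division points at most
        max_region apart."""
        counts = np.zeros(10_000, dtype=int)
        counts[1000:6000] = 12
        p = self.params(max_region=1000, min_region=100)
        regions = scan_chromosome(hist(counts), p)
        assert all(len(r) <= p.max_region for r in regions)
        covered = sum(len(r) for r in regions)
        assert covered >= 5000

    def test_linear_operation_count_in_chromosome_length(self):
        """Doubling the chromosome at fixed signal density at most doubles
        the number of sigma_B^2 evaluations."""
        def tiled(n_blocks):
            counts = np.zeros(n_blocks * 5000, dtype=np.int64)
            for i in range(n_blocks):
                counts[i * 5000 + 2000 : i * 5000 + 2300] = 20
            return hist(counts)

        p = self.params(min_supported_reads=15.0)
        s1, s2 = ScanStats(), ScanStats()
        scan_chromosome(tiled(20), p, s1)
        scan_chromosome(tiled(40), p, s2)
        assert s2.sigma_evaluations <= 2 * s1.sigma_evaluations
        assert s1.sigma_evaluations > 0
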