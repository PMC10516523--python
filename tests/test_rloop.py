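"""Window tiling, strand counting, imbalance tests, R-loop assembly,
RNase-H filtering."""

import math

import numpy as np
import pytest
from scipy import stats

from kaskit.coverage import CoverageTrack
from kaskit.intervals import GenomicInterval
from kaskit.nbstats import size_factors
from kaskit.rloop import (
    ImbalanceResult,
    StrandedWindow,
    bh_adjust,
    binomial_imbalance_test,
    call_rloops,
    count_strands,
    nb_imbalance_test,
    rloop_density_track,
    rnaseh_filter,
    tile_windows,
)

from .conftest import random_intervals


def win(start, end, plus, minus, chrom="chr1"):
    return StrandedWindow(GenomicInterval(chrom, start, end),
                          tuple(plus), tuple(minus))


class TestTileWindows:
    def test_trailing_below_half_dropped(self):
        out = tile_windows([GenomicInterval("chr1", 0, 1600)])
        assert [(w.start, w.end) for w in out] == [(0, 500), (500, 1000), (1000, 1500)]

    def test_trailing_at_half_kept(self):
        out = tile_windows([GenomicInterval("chr1", 0, 1750)])
        assert (out[-1].start, out[-1].end) == (1500, 1750)

    def test_overlapping_peaks_deduplicated(self):
        peaks = [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 0, 1000)]
        assert len(tile_windows(peaks)) == 2

    def test_windows_inside_peaks_with_bounded_width(self, rng):
        peaks = random_intervals(rng, 30, max_pos=100_000, max_width=5000)
        out = tile_windows(peaks, size=500, step=500)
        for w in out:
            assert any(p.start <= w.start and w.end <= p.end for p in peaks)
            assert 250 <= w.width <= 500

    def test_bad_step_raises(self):
        with pytest.raises(ValueError):
            tile_windows([], size=500, step=600)


class TestCountStrands:
    def test_hand_counts(self):
        plus = [GenomicInterval("chr1", 10, 160, strand="+")] * 7
        minus = [GenomicInterval("chr1", 10, 160, strand="-")] * 2
        (w,) = count_strands([GenomicInterval("chr1", 0, 500)], [plus], [minus])
        assert w.plus_counts == (7,) and w.minus_counts == (2,)

    def test_empty_window(self):
        (w,) = count_strands([GenomicInterval("chr1", 5000, 5500)],
                             [[GenomicInterval("chr1", 0, 100, strand="+")]],
                             [[]])
        assert w.plus_counts == (0,) and w.minus_counts == (0,)

    def test_replicate_mismatch_raises(self):
        with pytest.raises(ValueError):
            count_strands([], [[], []], [[]])

    def test_matches_brute_force(self, rng):
        windows = [GenomicInterval("chr1", s, s + 500)
                   for s in range(0, 5000, 500)]
        tags = random_intervals(rng, 400, max_pos=6000, max_width=150)
        out = count_strands(windows, [tags], [tags])
        for w, sw in zip(windows, out):
            want = sum(1 for t in tags if t.start < w.end and t.end > w.start)
            assert sw.plus_counts[0] == want == sw.minus_counts[0]


class TestSizeFactors:
    def test_doubled_sample(self, rng):
        base = rng.poisson(50, size=(100, 1)).astype(float) + 1
        mat = np.hstack([base, 2 * base])
        sf = size_factors(mat)
        np.testing.assert_allclose(sf, [1 / math.sqrt(2), math.sqrt(2)], rtol=1e-12)

    def test_single_sample_is_one(self, rng):
        mat = rng.poisson(30, size=(50, 1)) + 1
        assert size_factors(mat) == pytest.approx([1.0])

    def test_no_all_positive_feature_raises(self):
        with pytest.raises(ValueError, match="pseudo-count"):
            size_factors(np.array([[0, 5], [3, 0]]))

    def test_matches_direct_median_of_ratios(self, rng):
        mat = rng.negative_binomial(10, 0.2, size=(200, 4)).astype(float)
        keep = (mat > 0).all(axis=1)
        gm = np.exp(np.log(mat[keep]).mean(axis=1))
        want = [np.median(mat[keep, j] / gm) for j in range(4)]
        np.testing.assert_allclose(size_factors(mat), want, rtol=1e-12)


class TestBinomialTest:
    def test_balanced_is_one(self):
        p, fc = binomial_imbalance_test(win(0, 500, [15], [15]))
        assert p == 1.0 and fc == 0.0

    def test_zero_total_sentinel(self):
        p, fc = binomial_imbalance_test(win(0, 500, [0], [0]))
        assert (p, fc) == (1.0, 0.0)

    def test_matches_enumeration_oracle_half(self):
        w = win(0, 500, [30], [10])
        p, _ = binomial_imbalance_test(w, 0.5)
        # exhaustive enumeration: sum of P(X=k) <= P(X=30), n=40, p0=0.5
        pmf = [math.comb(40, k) * 0.5**40 for k in range(41)]
        want = sum(q for q in pmf if q <= pmf[30] * (1 + 1e-12))
        assert p == pytest.approx(want, abs=1e-12)

    def test_matches_enumeration_oracle_skewed_null(self):
        w = win(0, 500, [30], [10])
        p, _ = binomial_imbalance_test(w, 0.75)
        pmf = [math.comb(40, k) * 0.75**k * 0.25 ** (40 - k) for k in range(41)]
        want = sum(q for q in pmf if q <= pmf[30] * (1 + 1e-12))
        assert p == pytest.approx(want, abs=1e-12)
        assert p > 0.5   # 30/40 is near the expectation under p0 = 0.75

    def test_enumeration_equality_over_many_totals(self):
        for plus, minus in [(0, 5), (3, 3), (12, 38), (25, 25), (40, 10)]:
            n = plus + minus
            p, _ = binomial_imbalance_test(win(0, 500, [plus], [minus]), 0.5)
            pmf = [math.comb(n, k) * 0.5**n for k in range(n + 1)]
            want = min(1.0, sum(q for q in pmf if q <= pmf[plus] * (1 + 1e-12)))
            assert p == pytest.approx(want, abs=1e-12)


class TestBH:
    def test_hand_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_definition(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 50)))
            n = p.size
            order = np.argsort(p)
            scaled = p[order] * n / np.arange(1, n + 1)
            adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
            want = np.empty(n)
            want[order] = np.minimum(adj_sorted, 1.0)
            np.testing.assert_allclose(bh_adjust(p), want, rtol=1e-12)


class TestNbImbalance:
    def test_exact_balance_not_significant(self):
        windows = [win(s, s + 500, [50, 50], [50, 50]) for s in range(0, 10_000, 500)]
        res = nb_imbalance_test(windows, sf=np.ones(4))
        assert abs(res[0].log2fc) < 1e-9
        assert res[0].p_value > 0.9
        assert not res[0].significant

    def test_swapping_strands_negates_log2fc(self, rng):
        windows = [win(s, s + 500,
                       rng.poisson(60, 2).tolist(), rng.poisson(40, 2).tolist())
                   for s in range(0, 25_000, 500)]
        swapped = [StrandedWindow(w.window, w.minus_counts, w.plus_counts)
                   for w in windows]
        a = nb_imbalance_test(windows, sf=np.ones(4))
        b = nb_imbalance_test(swapped, sf=np.ones(4))
        for ra, rb in zip(a, b):
            assert ra.log2fc == pytest.approx(-rb.log2fc, abs=1e-9)
            assert ra.p_value == pytest.approx(rb.p_value, abs=1e-9)
            if ra.dominant_strand in "+-":
                assert {ra.dominant_strand, rb.dominant_strand} == {"+", "-"}

    def test_single_replicate_delegates_to_binomial(self):
        windows = [win(0, 500, [200], [50]), win(500, 1000, [30], [30])]
        res = nb_imbalance_test(windows, sf=np.ones(2))
        want_p, _ = binomial_imbalance_test(windows[0],
                                            expected_plus_fraction=230 / 310)
        assert res[0].p_value == pytest.approx(want_p)


class TestCallRloops:
    def res(self, start, strand, sig=True, lfc=2.0):
        return ImbalanceResult(GenomicInterval("chr1", start, start + 500),
                               lfc if strand == "+" else -lfc,
                               0.001, 0.01, strand, sig)

    def test_adjacent_same_strand_merge(self):
        results = [self.res(0, "+"), self.res(500, "+"), self.res(1000, "+")]
        (region,) = call_rloops(results)
        assert (region.interval.start, region.interval.end) == (0, 1500)
        assert region.n_windows == 3

    def test_opposite_strands_stay_separate(self):
        results = [self.res(0, "+"), self.res(500, "-")]
        regions = call_rloops(results)
        assert len(regions) == 2
        assert {r.dominant_strand for r in regions} == {"+", "-"}

    def test_non_significant_excluded(self):
        results = [self.res(0, "+"), self.res(500, "+", sig=False)]
        (region,) = call_rloops(results)
        assert region.interval.end == 500

    def test_matches_merge_oracle_on_random_patterns(self, rng):
        starts = np.arange(0, 50_000, 500)
        sig = rng.random(starts.size) < 0.3
        strands = np.where(rng.random(starts.size) < 0.5, "+", "-")
        results = [self.res(int(s), str(st), sig=bool(g))
                   for s, st, g in zip(starts, strands, sig)]
        regions = call_rloops(results)
        # oracle: walk runs of consecutive significant same-strand windows
        want = []
        i = 0
        while i < starts.size:
            if sig[i]:
                j = i
                while (j + 1 < starts.size and sig[j + 1]
                       and strands[j + 1] == strands[i]
                       and starts[j + 1] == starts[j] + 500):
                    j += 1
                want.append((int(starts[i]), int(starts[j]) + 500, strands[i]))
                i = j + 1
            else:
                i += 1
        got = [(r.interval.start, r.interval.end, r.dominant_strand)
               for r in regions]
        assert sorted(got) == sorted(want)


class TestDensityAndRnaseh:
    def test_absolute_difference(self):
        plus = CoverageTrack(50, {"chr1": np.array([10.0, 4.0])}, "RPKM")
        minus = CoverageTrack(50, {"chr1": np.array([4.0, 4.0])}, "RPKM")
        track = rloop_density_track(plus, minus)
        np.testing.assert_allclose(track.values["chr1"], [6.0, 0.0])

    def test_symmetry(self, rng):
        a = CoverageTrack(50, {"chr1": rng.uniform(0, 10, 100)}, "RPKM")
        b = CoverageTrack(50, {"chr1": rng.uniform(0, 10, 100)}, "RPKM")
        np.testing.assert_allclose(rloop_density_track(a, b).values["chr1"],
                                   rloop_density_track(b, a).values["chr1"])

    def test_mismatched_bin_raises(self):
        a = CoverageTrack(50, {"chr1": np.zeros(2)}, "RPKM")
        b = CoverageTrack(100, {"chr1": np.zeros(1)}, "RPKM")
        with pytest.raises(ValueError):
            rloop_density_track(a, b)

    def test_planted_ratio_fixture(self):
        """Exactly the regions with WT/treated >= 1.5 are sensitive."""
        ratios = [0.5, 1.0, 1.4, 1.5, 2.0, 3.0, 4.0, 1.49, 1.51, 10.0]
        n = len(ratios)
        wt_vals = np.full(n * 10, 6.0)
        tr_vals = np.concatenate([np.full(10, 6.0 / r) for r in ratios])
        wt = CoverageTrack(50, {"chr1": wt_vals}, "RPKM")
        tr = CoverageTrack(50, {"chr1": tr_vals}, "RPKM")
        regions = [GenomicInterval("chr1", i * 500, (i + 1) * 500)
                   for i in range(n)]
        sens, insens = rnaseh_filter(regions, wt, tr)
        want = {i for i, r in enumerate(ratios) if r >= 1.5}
        assert {r.start // 500 for r in sens} == want
        assert len(sens) + len(insens) == n

    def test_missing_chromosome_raises(self):
        wt = CoverageTrack(50, {"chr1": np.ones(10)}, "RPKM")
        with pytest.raises(KeyError):
            rnaseh_filter([GenomicInterval("chr2", 0, 100)], wt, wt)
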