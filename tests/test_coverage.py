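"""Coverage tracks, densities, metagene profiles, bedGraph round-trips."""

import numpy as np
import pytest

from kaskit.coverage import (
    bin_counts,
    extend_reads,
    metagene_profile,
    pair_to_fragment,
    read_bedgraph,
    region_density,
    rpkm_normalize,
    strand_split,
    write_bedgraph,
)
from kaskit.intervals import ChromSizes, GeneModel, GenomicInterval

from .conftest import random_intervals


def tag(chrom, start, end, strand="+"):
    return GenomicInterval(chrom, start, end, strand=strand)


class TestExtendReads:
    @pytest.mark.parametrize(
        "start,end,strand,want",
        [
            (100, 136, "+", (100, 250)),   # 5'->3' extension on plus
            (500, 536, "-", (386, 536)),   # mirrored on minus
            (30, 66, "-", (0, 66)),        # clipped at chromosome start
        ],
    )
    def test_extension_geometry(self, sizes, start, end, strand, want):
        (out,) = extend_reads([tag("chr1", start, end, strand)], sizes, 150)
        assert (out.start, out.end) == want

    def test_long_reads_not_truncated(self, sizes):
        t = tag("chr1", 100, 400)
        assert extend_reads([t], sizes, 150) == [t]

    def test_unknown_chromosome_raises(self, sizes):
        with pytest.raises(KeyError):
            extend_reads([tag("chrZ", 0, 36)], sizes)


class TestPairToFragment:
    def test_span_rule(self):
        frag = pair_to_fragment(tag("chr1", 100, 150, "+"), tag("chr1", 300, 350, "-"))
        assert (frag.start, frag.end) == (100, 350)

    def test_fully_overlapping_mates(self):
        frag = pair_to_fragment(tag("chr1", 100, 150, "+"), tag("chr1", 100, 150, "-"))
        assert (frag.start, frag.end) == (100, 150)

    def test_cross_chromosome_raises(self):
        with pytest.raises(ValueError):
            pair_to_fragment(tag("chr1", 0, 50, "+"), tag("chr2", 0, 50, "-"))

    def test_inverted_orientation_raises(self):
        with pytest.raises(ValueError):
            pair_to_fragment(tag("chr1", 100, 150, "-"), tag("chr1", 300, 350, "+"))

    def test_fragment_width_property(self, rng):
        for _ in range(1000):
            s1 = int(rng.integers(0, 5000))
            s2 = s1 + int(rng.integers(0, 500))
            m1 = tag("chr1", s1, s1 + 50, "+")
            m2 = tag("chr1", s2, s2 + 50, "-")
            frag = pair_to_fragment(m1, m2)
            assert frag.width == max(m1.end, m2.end) - min(m1.start, m2.start)


class TestBinCounts:
    def test_tag_hits_every_overlapped_bin(self, sizes):
        track = bin_counts([tag("chr1", 0, 150)], sizes, 50)
        assert track.values["chr1"][:4].tolist() == [1, 1, 1, 0]

    def test_stacked_tags(self, sizes):
        track = bin_counts([tag("chr1", 10, 20)] * 3, sizes, 50)
        assert track.values["chr1"][0] == 3

    def test_tag_beyond_chromosome_raises(self):
        small = ChromSizes({"chr1": 100})
        with pytest.raises(ValueError):
            bin_counts([tag("chr1", 50, 150)], small, 50)

    def test_matches_brute_force_overlap_counts(self, sizes, rng):
        tags = random_intervals(rng, 300, max_pos=5000)
        track = bin_counts(tags, sizes, 50)
        for b in range(120):
            lo, hi = b * 50, (b + 1) * 50
            want = sum(1 for t in tags if t.start < hi and t.end > lo)
            assert track.values["chr1"][b] == want

    def test_sum_at_least_tag_count(self, sizes, rng):
        tags = random_intervals(rng, 200, max_pos=5000)
        track = bin_counts(tags, sizes, 50)
        assert track.values["chr1"].sum() >= len(tags)


class TestRpkm:
    def test_hand_value(self, sizes):
        track = bin_counts([tag("chr1", 0, 50)] * 5, sizes, 50)
        rpkm = rpkm_normalize(track, 1_000_000)
        assert rpkm.values["chr1"][0] == pytest.approx(100.0)

    def test_zero_library_raises(self, sizes):
        track = bin_counts([], sizes, 50)
        with pytest.raises(ValueError):
            rpkm_normalize(track, 0)

    def test_doubling_library_halves_values(self, sizes, rng):
        tags = random_intervals(rng, 100, max_pos=5000)
        track = bin_counts(tags, sizes, 50)
        a = rpkm_normalize(track, 1000).values["chr1"]
        b = rpkm_normalize(track, 2000).values["chr1"]
        np.testing.assert_allclose(a, 2 * b)


class TestRegionDensity:
    def test_hand_value(self, sizes):
        tags = [tag("chr1", 1000 + i, 1010 + i) for i in range(40)]
        d = region_density(tags, GenomicInterval("chr1", 500, 2500), 1_000_000)
        assert d.value == pytest.approx(20.0)
        assert d.tag_count == 40

    def test_no_overlap_is_zero(self, sizes):
        d = region_density([tag("chr1", 0, 10)], GenomicInterval("chr1", 5000, 6000), 1000)
        assert d.value == 0.0

    def test_agrees_with_binned_rpkm_for_aligned_regions(self, sizes, rng):
        # tags fully inside single bins, region spanning whole bins
        tags = []
        for _ in range(200):
            b = int(rng.integers(0, 40))
            tags.append(tag("chr1", b * 50 + 5, b * 50 + 45))
        lib = len(tags)
        region = GenomicInterval("chr1", 0, 2000)
        d = region_density(tags, region, lib)
        rpkm = rpkm_normalize(bin_counts(tags, sizes, 50), lib)
        assert d.value == pytest.approx(rpkm.values["chr1"][:40].mean())

    def test_union_of_equal_regions_is_mean_density(self, sizes, rng):
        tags = random_intervals(rng, 500, max_pos=4000)
        lib = len(tags)
        r1 = GenomicInterval("chr1", 0, 1000)
        r2 = GenomicInterval("chr1", 3000, 4000)
        union_count = (region_density(tags, r1, lib).tag_count
                       + region_density(tags, r2, lib).tag_count)
        union_value = union_count * 1e9 / (2000 * lib)
        mean_value = (region_density(tags, r1, lib).value
                      + region_density(tags, r2, lib).value) / 2
        # equal widths: density of the union equals the mean of densities
        # (up to tags overlapping both regions, impossible here)
        assert union_value == pytest.approx(mean_value)


class TestStrandSplit:
    def test_partition_sizes(self):
        tags = [tag("chr1", 0, 10, "+")] * 3 + [tag("chr1", 0, 10, "-")] * 2
        plus, minus = strand_split(tags)
        assert (len(plus), len(minus)) == (3, 2)

    def test_unstranded_rejected(self):
        with pytest.raises(ValueError):
            strand_split([tag("chr1", 0, 10, ".")])

    def test_conservation(self, rng):
        tags = random_intervals(rng, 500, stranded=True)
        plus, minus = strand_split(tags)
        assert len(plus) + len(minus) == len(tags)
        assert all(t.strand == "+" for t in plus)
        assert all(t.strand == "-" for t in minus)


class TestMetageneProfile:
    def make_uniform_track(self, sizes, value=3.0, bin_size=50):
        from kaskit.coverage import CoverageTrack
        values = {c: np.full(-(-l // bin_size), value) for c, l in sizes.items()}
        return CoverageTrack(bin_size=bin_size, values=values, normalization="RPKM")

    def test_constant_field_gives_constant_profile(self, sizes, simple_genes):
        track = self.make_uniform_track(sizes)
        mat, names = metagene_profile(track, simple_genes, sizes)
        assert mat.shape == (2, 60 + 100 + 60)
        np.testing.assert_allclose(mat, 3.0)

    def test_spike_lands_in_first_body_column(self, sizes):
        track = self.make_uniform_track(sizes, 0.0)
        track.values["chr1"][200:210] = 7.0   # 10000-10500
        gene = GeneModel(GenomicInterval("chr1", 10_000, 20_000, strand="+"), "g")
        mat, _ = metagene_profile(track, [gene], sizes)
        body = mat[0, 60:160]
        assert body[:5].min() > 0
        assert body[10:].max() == 0.0

    def test_strand_symmetry(self, sizes):
        # mirrored signal on a mirrored gene gives the identical row
        track_p = self.make_uniform_track(sizes, 0.0)
        track_p.values["chr1"][240:260] = 5.0
        gene_p = GeneModel(GenomicInterval("chr1", 10_000, 20_000, strand="+"), "gp")
        mat_p, _ = metagene_profile(track_p, [gene_p], sizes)

        track_m = self.make_uniform_track(sizes, 0.0)
        # mirror about gene centre 15000: [12000,13000) -> [17000,18000)
        track_m.values["chr1"][340:360] = 5.0
        gene_m = GeneModel(GenomicInterval("chr1", 10_000, 20_000, strand="-"), "gm")
        mat_m, _ = metagene_profile(track_m, [gene_m], sizes)
        np.testing.assert_allclose(mat_p[0], mat_m[0])

    def test_short_gene_skipped_with_warning(self, sizes):
        track = self.make_uniform_track(sizes)
        short = GeneModel(GenomicInterval("chr1", 10_000, 10_050, strand="+"), "tiny")
        ok = GeneModel(GenomicInterval("chr1", 20_000, 30_000, strand="+"), "ok")
        with pytest.warns(UserWarning):
            mat, names = metagene_profile(track, [short, ok], sizes)
        assert names == ["ok"]


class TestBedgraph:
    def test_run_length_collapse(self, tmp_path):
        from kaskit.coverage import CoverageTrack
        track = CoverageTrack(50, {"chr1": np.array([1, 1, 2])})
        p = tmp_path / "t.bg"
        write_bedgraph(track, p)
        assert p.read_text() == "chr1\t0\t100\t1\nchr1\t100\t150\t2\n"

    def test_suppress_zero(self, tmp_path):
        from kaskit.coverage import CoverageTrack
        track = CoverageTrack(50, {"chr1": np.zeros(4)})
        p = tmp_path / "t.bg"
        write_bedgraph(track, p, suppress_zero=True)
        assert p.read_text() == ""

    def test_round_trip(self, tmp_path, sizes, rng):
        tags = random_intervals(rng, 300, max_pos=5000)
        track = bin_counts(tags, sizes, 50)
        p = tmp_path / "t.bg"
        write_bedgraph(track, p)
        back = read_bedgraph(p, sizes, 50)
        np.testing.assert_allclose(back.values["chr1"], track.values["chr1"])
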