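import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromacoop.intervals import (
    GenomeSpec,
    IntervalIndex,
    center,
    center_in,
    common_sites_each,
    common_sites_one,
    nearest_tss,
    randomize_peaks,
    reduce_merge,
    three_way_overlap,
    UNASSIGNED,
)
from chromacoop.io_formats import Interval, PeakRecord, TssRecord

from conftest import (
    brute_common_each,
    brute_common_one,
    brute_nearest_tss,
    random_peaks,
    random_tss,
)


class TestCenter:
    def test_midpoint(self):
        assert center(PeakRecord("chr1", 100, 200)) == 150

    def test_floor(self):
        assert center(PeakRecord("chr1", 100, 201)) == 150

    def test_summit_wins(self):
        assert center(PeakRecord("chr1", 100, 200, summit_offset=30)) == 130

    def test_interval_midpoint(self):
        assert center(Interval("chr1", 100, 200)) == 150


class TestCenterIn:
    def test_inside(self):
        a = PeakRecord("chr1", 100, 200)
        assert center_in(a, Interval("chr1", 140, 160))

    def test_boundary_start_is_in(self):
        a = PeakRecord("chr1", 100, 200)
        assert center_in(a, Interval("chr1", 150, 160))

    def test_boundary_end_is_out(self):
        a = PeakRecord("chr1", 100, 200)
        assert not center_in(a, Interval("chr1", 140, 150))

    def test_outside(self):
        a = PeakRecord("chr1", 100, 200)
        assert not center_in(a, Interval("chr1", 160, 300))

    def test_chromosome_mismatch(self):
        a = PeakRecord("chr1", 100, 200)
        assert not center_in(a, Interval("chr2", 100, 200))


class TestCommonSites:
    def test_one_center_example(self):
        a = [PeakRecord("chr1", 100, 200)]
        b = [PeakRecord("chr1", 140, 160)]
        assert len(common_sites_one(a, b)) == 1

    def test_disjoint_empty(self):
        a = [PeakRecord("chr1", 0, 10)]
        b = [PeakRecord("chr1", 100, 110)]
        assert common_sites_one(a, b) == []

    def test_each_center_example(self):
        assert common_sites_each(
            PeakRecord("chr1", 100, 200), PeakRecord("chr1", 140, 160)
        )

    def test_each_center_asymmetric_fails(self):
        assert not common_sites_each(
            PeakRecord("chr1", 100, 200), PeakRecord("chr1", 190, 400)
        )

    def test_matches_brute_force(self, small_genome):
        rng = np.random.default_rng(11)
        a = random_peaks(rng, 200, small_genome, prefix="a")
        b = random_peaks(rng, 200, small_genome, prefix="b")
        got = {(x.name, y.name) for x, y in common_sites_one(a, b)}
        want = {(x.name, y.name) for x, y in brute_common_one(a, b)}
        assert got == want

    def test_each_implies_one(self, small_genome):
        # each-center is strictly stronger than one-center on random pairs
        rng = np.random.default_rng(12)
        for _ in range(10_000):
            s1, s2 = rng.integers(0, 5000, size=2)
            w1, w2 = rng.integers(10, 400, size=2)
            a = PeakRecord("chr1", int(s1), int(s1 + w1))
            b = PeakRecord("chr1", int(s2), int(s2 + w2))
            if common_sites_each(a, b):
                assert brute_common_one([a], [b])

    def test_each_exhaustive_on_random_set(self, small_genome):
        rng = np.random.default_rng(13)
        peaks = random_peaks(rng, 50, small_genome)
        one = {(x.name, y.name) for x, y in common_sites_one(peaks, peaks)}
        for a in peaks:
            for b in peaks:
                assert common_sites_each(a, b) == brute_common_each(a, b)
                if common_sites_each(a, b):
                    assert (a.name, b.name) in one


class TestReduceMerge:
    def test_overlap_merges(self):
        got = reduce_merge([Interval("c", 10, 60), Interval("c", 50, 100)])
        assert got == [Interval("c", 10, 100)]

    def test_adjacent_merges(self):
        got = reduce_merge([Interval("c", 10, 20), Interval("c", 20, 30)])
        assert got == [Interval("c", 10, 30)]

    def test_chromosomes_separate(self):
        got = reduce_merge([Interval("c1", 10, 20), Interval("c2", 10, 20)])
        assert len(got) == 2

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 50)),
            min_size=0,
            max_size=30,
        )
    )
    def test_idempotent_sorted_disjoint_coverage(self, spans):
        ivs = [Interval("c", s, s + w) for s, w in spans]
        once = reduce_merge(ivs)
        assert reduce_merge(once) == once
        assert once == sorted(once, key=lambda iv: iv.start)
        for prev, cur in zip(once, once[1:]):
            assert cur.start > prev.end  # disjoint and non-adjacent
        covered = set()
        for iv in ivs:
            covered.update(range(iv.start, iv.end))
        merged_cov = set()
        for iv in once:
            merged_cov.update(range(iv.start, iv.end))
        assert merged_cov == covered


class TestThreeWayOverlap:
    def test_anchor_with_er_only(self):
        anchors = [Interval("c", 1000, 2000)]
        er = [PeakRecord("c", 1400, 1600)]
        (ev,) = three_way_overlap(anchors, er, [])
        assert ev.anchor_present and ev.er_present and not ev.hsf1_present

    def test_anchor_with_both(self):
        anchors = [Interval("c", 1000, 2000)]
        er = [PeakRecord("c", 1400, 1600)]
        hsf1 = [PeakRecord("c", 1450, 1650)]
        (ev,) = three_way_overlap(anchors, er, hsf1)
        assert ev.er_present and ev.hsf1_present

    def test_peak_only_cobinding_pair(self):
        er = [PeakRecord("c", 100, 300)]
        hsf1 = [PeakRecord("c", 150, 320)]
        (ev,) = three_way_overlap([], er, hsf1)
        assert ev.er_present and ev.hsf1_present and not ev.anchor_present
        assert ev.interval == Interval("c", 100, 320)

    def test_peak_rule_one_is_laxer(self):
        # HSF1 center inside ER peak, but ER center outside HSF1 peak
        er = [PeakRecord("c", 100, 400)]
        hsf1 = [PeakRecord("c", 110, 160)]
        (each_ev,) = [
            e for e in three_way_overlap([], er, hsf1, "each") if e.er_present
        ]
        assert not each_ev.hsf1_present
        one_evs = three_way_overlap([], er, hsf1, "one")
        assert any(e.er_present and e.hsf1_present for e in one_evs)

    def test_unreduced_anchors_rejected(self):
        anchors = [Interval("c", 0, 100), Interval("c", 50, 150)]
        with pytest.raises(AssertionError):
            three_way_overlap(anchors, [], [])

    def test_peak_in_anchor_needs_mutual_centers(self):
        # peak center inside anchor, but anchor midpoint NOT inside peak:
        # the peak does not attach and is emitted as a peak-only region
        anchors = [Interval("c", 1000, 2000)]
        er = [PeakRecord("c", 1100, 1300)]
        regions = three_way_overlap(anchors, er, [])
        anchor_ev = next(e for e in regions if e.anchor_present)
        assert not anchor_ev.er_present
        peak_ev = next(e for e in regions if not e.anchor_present)
        assert peak_ev.er_present and peak_ev.interval == Interval("c", 1100, 1300)


class TestNearestTss:
    TSS = [
        TssRecord("gA", "c", "+", 1000),
        TssRecord("gB", "c", "+", 2100),
    ]

    def test_nearest_plus_strand(self):
        gene, dist = nearest_tss(Interval("c", 1400, 1600), self.TSS)
        assert (gene, dist) == ("gA", 500)

    def test_tie_breaks_lexically(self):
        table = [TssRecord("gB", "c", "+", 1000), TssRecord("gA", "c", "+", 2000)]
        gene, _ = nearest_tss(Interval("c", 1400, 1600), table)
        assert gene == "gA"

    def test_minus_strand_sign(self):
        table = [TssRecord("g", "c", "-", 2000)]
        gene, dist = nearest_tss(Interval("c", 1400, 1600), table)
        # midpoint 1500 is downstream of a minus-strand TSS at 2000
        assert dist == 500

    def test_empty_table_error(self):
        with pytest.raises(ValueError):
            nearest_tss(Interval("c", 0, 10), [])

    def test_no_same_chromosome_unassigned(self):
        table = [TssRecord("g", "other", "+", 5)]
        assert nearest_tss(Interval("c", 0, 10), table) == UNASSIGNED

    def test_matches_brute_force(self, small_genome):
        rng = np.random.default_rng(21)
        table = random_tss(rng, 100, small_genome)
        for _ in range(1000):
            chrom, length = small_genome.chromosomes[
                int(rng.integers(0, 2))
            ]
            s = int(rng.integers(0, length - 100))
            region = Interval(chrom, s, s + 100)
            want = brute_nearest_tss(region, table)
            got = nearest_tss(region, table)
            assert got == (want if want is not None else UNASSIGNED)


class TestRandomizePeaks:
    def test_degenerate_full_width(self):
        g = GenomeSpec.from_pairs([("c", 100)])
        (p,) = randomize_peaks([PeakRecord("c", 0, 100)], g, seed=0)
        assert (p.start, p.end) == (0, 100)

    def test_conserves_width_chrom_summit(self, small_genome):
        rng = np.random.default_rng(31)
        peaks = random_peaks(rng, 100, small_genome)
        shuffled = randomize_peaks(peaks, small_genome, seed=5)
        for old, new in zip(peaks, shuffled):
            assert new.chrom == old.chrom
            assert new.width == old.width
            assert new.summit_offset == old.summit_offset

    def test_peak_longer_than_chromosome(self):
        g = GenomeSpec.from_pairs([("c", 50)])
        with pytest.raises(ValueError):
            randomize_peaks([PeakRecord("c", 0, 40)], GenomeSpec.from_pairs([("c", 30)]), seed=0)
        randomize_peaks([PeakRecord("c", 0, 40)], g, seed=0)  # fits

    def test_seed_determinism(self, small_genome):
        rng = np.random.default_rng(32)
        peaks = random_peaks(rng, 50, small_genome)
        a = randomize_peaks(peaks, small_genome, seed=9)
        b = randomize_peaks(peaks, small_genome, seed=9)
        assert a == b

    def test_uniform_start_distribution(self):
        # chi-square GOF on 10^4 draws of a width-10 peak on a 110 bp chrom
        from scipy.stats import chisquare

        g = GenomeSpec.from_pairs([("c", 110)])
        peak = PeakRecord("c", 0, 10)
        rng = np.random.default_rng(33)
        starts = [
            randomize_peaks([peak], g, rng=rng)[0].start for _ in range(10_000)
        ]
        counts = np.bincount(starts, minlength=101)
        assert len(counts) == 101  # admissible starts 0..100
        _, p = chisquare(counts)
        assert p > 0.01


class TestIntervalIndex:
    def test_insertion_order_independent(self):
        ivs1 = [Interval("c", 0, 10), Interval("c", 5, 20), Interval("d", 0, 5)]
        ivs2 = list(reversed(ivs1))
        i1, i2 = IntervalIndex(ivs1), IntervalIndex(ivs2)
        for pos in range(0, 25):
            assert set(i1.containing_point("c", pos)) == set(
                i2.containing_point("c", pos)
            )

    def test_overlapping_query(self):
        idx = IntervalIndex([Interval("c", 0, 10), Interval("c", 20, 30)])
        assert idx.overlapping("c", 8, 22) == [
            Interval("c", 0, 10),
            Interval("c", 20, 30),
        ]
        assert idx.overlapping("c", 10, 20) == []
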