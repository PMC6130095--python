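import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import replisig as rs
from replisig.regions import GenomicInterval, ReplicationDomain, TimingProfile


def linear_profile(slope_per_mb, length=200_000, bin_width=1_000, intercept=100.0):
    starts = np.arange(0, length, bin_width)
    mids = starts + bin_width / 2
    return TimingProfile.from_frame(pd.DataFrame({
        "chrom": "chr1", "start": starts, "end": starts + bin_width,
        "timing": intercept + slope_per_mb * mids / 1e6,
    }))


class TestDeriveDomains:
    def test_uniform_rising_slope_gives_all_right(self):
        domains = rs.derive_domains_from_timing(linear_profile(500.0))
        assert len(domains) == 10
        assert all(d.direction == "right" for d in domains)

    def test_uniform_falling_slope_gives_all_left(self):
        domains = rs.derive_domains_from_timing(linear_profile(-500.0))
        assert all(d.direction == "left" for d in domains)

    def test_flat_profile_emits_no_domains(self):
        assert rs.derive_domains_from_timing(linear_profile(0.0)) == []

    def test_triangular_profile_splits_by_slope_sign(self):
        # rise at +400 rtu/Mb to the midpoint, then fall at -400
        length, bw = 400_000, 1_000
        starts = np.arange(0, length, bw)
        mids = starts + bw / 2
        apex = 190_000  # mid-window, so one window straddles the peak
        timing = 100 + 400.0 * (apex - np.abs(mids - apex)) / 1e6
        profile = TimingProfile.from_frame(pd.DataFrame({
            "chrom": "chr1", "start": starts, "end": starts + bw, "timing": timing}))
        domains = rs.derive_domains_from_timing(profile, slope_threshold=250.0)
        # brute-force slope per 20-kb window decides the expected direction
        expected = {}
        for w0 in range(0, length - 20_000 + 1, 20_000):
            sel = (mids >= w0) & (mids < w0 + 20_000)
            slope = np.polyfit(mids[sel] / 1e6, timing[sel], 1)[0]
            if abs(slope) >= 250:
                expected[w0] = "right" if slope > 0 else "left"
        got = {d.interval.start: d.direction for d in domains}
        assert got == expected
        # the apex window is removed, both halves present
        assert "right" in got.values() and "left" in got.values()
        assert len(got) < length // 20_000

    def test_mean_timing_annotation(self):
        domains = rs.derive_domains_from_timing(linear_profile(500.0))
        assert domains[0].timing < domains[-1].timing

    def test_short_chromosome_skipped_with_warning(self):
        profile = TimingProfile.from_frame(pd.DataFrame({
            "chrom": ["chr1"], "start": [0], "end": [1000], "timing": [1.0]}))
        with pytest.warns(UserWarning, match="<2 timing bins"):
            assert rs.derive_domains_from_timing(profile) == []

    def test_non_monotone_bins_rejected(self):
        with pytest.raises(ValueError, match="overlapping or non-monotone"):
            TimingProfile.from_frame(pd.DataFrame({
                "chrom": "chr1", "start": [0, 500], "end": [1000, 1500],
                "timing": [1.0, 2.0]}))


class TestOriginBins:
    def test_two_origins_share_midpoint_without_crossing(self):
        origins = [GenomicInterval("chr1", 99_500, 100_500),
                   GenomicInterval("chr1", 109_500, 110_500)]
        bins = rs.build_origin_bins(origins, bin_width=1_000, max_bins=1_000)
        between = [b for b in bins if 100_000 <= b.interval.start < 110_000]
        right_of_first = [b for b in between if b.side == "right_of_origin"
                          and b.interval.start < 105_000]
        left_of_second = [b for b in between if b.side == "left_of_origin"]
        assert len(right_of_first) == 5
        assert len(left_of_second) == 5
        assert all(b.interval.end <= 105_000 for b in right_of_first)
        assert all(b.interval.start >= 105_000 for b in left_of_second)

    def test_single_origin_gets_max_bins_where_space_allows(self):
        origins = [GenomicInterval("chr1", 1_499_500, 1_500_500)]
        bins = rs.build_origin_bins(origins, chrom_sizes={"chr1": 3_000_000})
        assert sum(b.side == "left_of_origin" for b in bins) == 1_000
        assert sum(b.side == "right_of_origin" for b in bins) == 1_000
        assert all(b.interval.width == 1_000 for b in bins)

    def test_origin_at_chromosome_start_has_no_left_bins(self):
        bins = rs.build_origin_bins([GenomicInterval("chr1", 0, 100)],
                                    max_bins=10, chrom_sizes={"chr1": 100_000})
        assert all(b.side == "right_of_origin" for b in bins)

    def test_directions_point_outward(self):
        bins = rs.build_origin_bins([GenomicInterval("chr1", 49_500, 50_500)],
                                    max_bins=5, chrom_sizes={"chr1": 100_000})
        for b in bins:
            expected = "left" if b.side == "left_of_origin" else "right"
            assert b.inferred_direction == expected

    def test_overlapping_origins_merge_with_warning(self):
        with pytest.warns(UserWarning, match="merged"):
            rs.build_origin_bins([GenomicInterval("chr1", 0, 1000),
                                  GenomicInterval("chr1", 500, 1500)], max_bins=2)

    @given(st.lists(st.integers(5_000, 995_000), min_size=2, max_size=6, unique=True))
    @settings(max_examples=30, deadline=None)
    def test_bins_from_adjacent_origins_never_overlap(self, midpoints):
        origins = [GenomicInterval("chr1", m - 10, m + 10) for m in sorted(midpoints)]
        bins = rs.build_origin_bins(origins, bin_width=1_000, max_bins=50,
                                    chrom_sizes={"chr1": 1_000_000})
        ivs = sorted((b.interval.start, b.interval.end) for b in bins)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2


def _domain(start, timing, chrom="chr1", direction="left"):
    return ReplicationDomain(GenomicInterval(chrom, start, start + 1000), direction, timing)


class TestQuartiles:
    def test_default_orientation_low_rtu_is_early(self):
        domains = [_domain(1000 * i, float(i + 1)) for i in range(8)]
        q = rs.assign_timing_quartiles(domains)
        assert {q[domains[0]], q[domains[1]]} == {"Q1"}
        assert {q[domains[6]], q[domains[7]]} == {"Q4"}

    def test_high_is_early_dialect_inverts(self):
        domains = [_domain(1000 * i, float(i + 1)) for i in range(8)]
        q = rs.assign_timing_quartiles(domains, higher_rtu_is_earlier=True)
        assert {q[domains[7]], q[domains[6]]} == {"Q1"}
        assert {q[domains[0]], q[domains[1]]} == {"Q4"}

    def test_four_domains_one_per_quartile(self):
        domains = [_domain(1000 * i, float(i)) for i in range(4)]
        assert sorted(rs.assign_timing_quartiles(domains).values()) == [
            "Q1", "Q2", "Q3", "Q4"]

    def test_five_domains_split_two_one_one_one(self):
        domains = [_domain(1000 * i, float(i)) for i in range(5)]
        sizes = pd.Series(list(rs.assign_timing_quartiles(domains).values())).value_counts()
        assert sorted(sizes) == [1, 1, 1, 2]

    def test_quartile_balance_property(self):
        for n in (4, 7, 10, 41, 100):
            domains = [_domain(1000 * i, float(i % 13)) for i in range(n)]
            counts = pd.Series(
                list(rs.assign_timing_quartiles(domains).values())).value_counts()
            assert all(abs(c - n / 4) < 1 for c in counts)

    def test_identical_timings_warn(self):
        domains = [_domain(1000 * i, 5.0) for i in range(4)]
        with pytest.warns(UserWarning, match="identical"):
            rs.assign_timing_quartiles(domains)


class TestExclusions:
    def test_middle_mask_splits_interval(self):
        out = rs.apply_exclusions([GenomicInterval("c", 0, 100)],
                                  [GenomicInterval("c", 40, 60)])
        assert out == [GenomicInterval("c", 0, 40), GenomicInterval("c", 60, 100)]

    def test_full_mask_empties_interval(self):
        assert rs.apply_exclusions([GenomicInterval("c", 10, 20)],
                                   [GenomicInterval("c", 0, 100)]) == []

    def test_adjacent_masks(self):
        out = rs.apply_exclusions([GenomicInterval("c", 0, 40)],
                                  [GenomicInterval("c", 10, 20),
                                   GenomicInterval("c", 20, 30)])
        assert out == [GenomicInterval("c", 0, 10), GenomicInterval("c", 30, 40)]

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_per_base_oracle_and_length_conservation(self, data):
        n_iv = data.draw(st.integers(1, 4))
        n_mask = data.draw(st.integers(0, 5))
        def draw_iv():
            s = data.draw(st.integers(0, 9_000))
            w = data.draw(st.integers(1, 1_000))
            return GenomicInterval("c", s, s + w)
        ivs = sorted({draw_iv() for _ in range(n_iv)})
        # inputs must not overlap for the length identity to hold
        merged_in = []
        for iv in ivs:
            if merged_in and iv.start < merged_in[-1].end:
                continue
            merged_in.append(iv)
        masks = [draw_iv() for _ in range(n_mask)]
        out = rs.apply_exclusions(merged_in, masks)
        covered = np.zeros(10_001, dtype=bool)
        for iv in merged_in:
            covered[iv.start:iv.end] = True
        masked = np.zeros(10_001, dtype=bool)
        for m in masks:
            masked[m.start:m.end] = True
        expected = covered & ~masked
        got = np.zeros(10_001, dtype=bool)
        for iv in out:
            assert not got[iv.start:iv.end].any()  # outputs disjoint
            got[iv.start:iv.end] = True
        assert (got == expected).all()
        overlap = (covered & masked).sum()
        assert sum(iv.width for iv in out) + overlap == sum(iv.width for iv in merged_in)


class TestRandomizeDomains:
    def _domains(self):
        return [ReplicationDomain(GenomicInterval("chr1", 1000 * i, 1000 * i + 500),
                                  "left" if i % 2 else "right", float(i))
                for i in range(10)]

    def test_deterministic_per_seed(self):
        d = self._domains()
        sizes = {"chr1": 100_000}
        assert rs.randomize_domains(d, sizes, seed=7) == rs.randomize_domains(d, sizes, seed=7)
        assert rs.randomize_domains(d, sizes, seed=7) != rs.randomize_domains(d, sizes, seed=8)

    def test_widths_and_annotations_preserved_without_overlap(self):
        d = self._domains()
        out = rs.randomize_domains(d, {"chr1": 100_000}, seed=3)
        assert sorted(x.interval.width for x in out) == sorted(x.interval.width for x in d)
        assert sorted((x.direction, x.timing) for x in out) == sorted(
            (x.direction, x.timing) for x in d)
        ivs = sorted((x.interval.start, x.interval.end) for x in out)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2

    def test_impossible_placement_raises(self):
        d = self._domains()
        with pytest.raises(ValueError, match="do not fit"):
            rs.randomize_domains(d, {"chr1": 4_000}, seed=1)
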