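import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fragmetrics import (
    CNARecord,
    GenomicInterval,
    coverage,
    cytosine_free_windows,
    dedupe_and_filter_records,
    flank_and_intersect,
    intersect_intervals,
    probe_gap_filter,
    revcomp,
    threshold_low_cna,
)
from fragmetrics.regions import (
    CoverageTrack,
    length_weighted_percentile,
    read_bed,
    write_bed,
)

from _oracles import (
    brute_coverage_array,
    brute_cytosine_free,
    brute_intersect_mask,
    brute_percentile_count,
    brute_probe_gap_drop,
    mask_to_intervals,
)


def random_intervals(rng, n, chrom="chr1", span=100_000, max_len=5_000):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span - 1))
        end = start + int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, min(end, span)))
    return out


class TestCoverage:
    def test_two_overlapping_intervals(self):
        track = coverage(
            [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 5, 15)]
        )
        assert track.runs == (
            ("chr1", 0, 5, 1),
            ("chr1", 5, 10, 2),
            ("chr1", 10, 15, 1),
        )

    def test_empty_input(self):
        assert coverage([]).runs == ()

    def test_gap_between_intervals_is_explicit_zero_run(self):
        track = coverage(
            [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)]
        )
        assert ("chr1", 10, 20, 0) in track.runs

    def test_matches_brute_force_per_base(self):
        rng = np.random.default_rng(31)
        intervals = random_intervals(rng, 1_000)
        track = coverage(intervals)
        arr = brute_coverage_array(intervals, "chr1", 100_000)
        recon = np.zeros(100_000, dtype=np.int64)
        for chrom, start, end, count in track.runs:
            recon[start:end] = count
        first = min(iv.start for iv in intervals)
        last = max(iv.end for iv in intervals)
        assert np.array_equal(recon[first:last], arr[first:last])


class TestDedupeAndFilter:
    def test_planted_violations_dropped_with_counts(self):
        records = [
            CNARecord("s1", "chr1", 0, 100),
            CNARecord("s1", "chr1", 0, 100),  # duplicate (sample, region)
            CNARecord("s2", "chr1", 0, 100),  # same region, other sample: kept
            CNARecord("s3", "chr1", 50, 150, is_cell_line=True),
            CNARecord("s4", "chr1", 50, 150, has_total_cn=False),
            CNARecord("s5", "chr2", 10, 20, has_minor_allele=False),
        ]
        kept, counts = dedupe_and_filter_records(records)
        assert [(iv.chrom, iv.start, iv.end, iv.payload) for iv in kept] == [
            ("chr1", 0, 100, "s1"),
            ("chr1", 0, 100, "s2"),
        ]
        assert counts == {
            "cell_line": 1,
            "incomplete": 2,
            "duplicate": 1,
            "kept": 2,
        }


class TestThresholdLowCNA:
    def test_hard_max_keeps_low_runs_only(self):
        track = CoverageTrack(
            (("chr1", 0, 10, 1), ("chr1", 10, 20, 40), ("chr1", 20, 30, 2))
        )
        kept = threshold_low_cna(track, hard_max=34)
        assert [(iv.start, iv.end) for iv in kept] == [(0, 10), (20, 30)]

    def test_all_below_cut_merges_to_full_span(self):
        track = CoverageTrack(
            (("chr1", 0, 10, 3), ("chr1", 10, 20, 5), ("chr1", 20, 30, 3))
        )
        kept = threshold_low_cna(track, hard_max=34)
        assert [(iv.start, iv.end) for iv in kept] == [(0, 30)]

    def test_hard_max_at_maximum_count_is_a_no_op_bound(self):
        rng = np.random.default_rng(5)
        intervals = random_intervals(rng, 50, span=10_000)
        track = coverage(intervals)
        kept = threshold_low_cna(track, hard_max=max(r[3] for r in track.runs))
        lo = min(iv.start for iv in intervals)
        hi = max(iv.end for iv in intervals)
        assert [(iv.start, iv.end) for iv in kept] == [(lo, hi)]

    def test_percentile_matches_brute_force_per_base(self):
        rng = np.random.default_rng(41)
        intervals = random_intervals(rng, 200, span=50_000)
        track = coverage(intervals)
        counts = np.array([r[3] for r in track.runs])
        lengths = np.array([r[2] - r[1] for r in track.runs])
        derived = length_weighted_percentile(track, 0.10)
        assert derived == brute_percentile_count(counts, lengths, 0.10)

    def test_empty_track_is_empty_result(self):
        assert threshold_low_cna(CoverageTrack(()), hard_max=10) == []


class TestProbeGapFilter:
    def test_small_candidate_with_close_probes_kept(self):
        cand = GenomicInterval("chr1", 0, 5_000)
        kept = probe_gap_filter([cand], {"chr1": [1_000, 4_000]})
        assert kept == [cand]

    def test_large_internal_gap_drops_candidate(self):
        cand = GenomicInterval("chr1", 0, 30_000)
        assert probe_gap_filter([cand], {"chr1": [1_000, 25_000]}) == []

    def test_chromosome_without_probes_drops_all_with_warning(self):
        cand = GenomicInterval("chrX", 0, 100)
        with pytest.warns(UserWarning, match="no probes"):
            assert probe_gap_filter([cand], {"chr1": [50]}) == []

    def test_matches_brute_force_gap_scan(self):
        rng = np.random.default_rng(51)
        probes = {"chr1": sorted(rng.integers(0, 100_000, 40).tolist())}
        candidates = random_intervals(rng, 200, span=100_000, max_len=30_000)
        kept = probe_gap_filter(candidates, probes, max_gap=10_000)
        expected = [
            c
            for c in candidates
            if not brute_probe_gap_drop(c, probes["chr1"], 10_000)
        ]
        assert kept == expected


class TestFlankAndIntersect:
    def test_apex_window_clipped_to_region(self):
        out = flank_and_intersect(
            [("chr1", 1_000)], [GenomicInterval("chr1", 0, 2_000)], flank=65
        )
        assert [(iv.start, iv.end) for iv in out] == [(935, 1_066)]

    def test_apex_outside_all_regions_excluded(self):
        out = flank_and_intersect(
            [("chr1", 5_000)], [GenomicInterval("chr1", 0, 2_000)], flank=65
        )
        assert out == []

    def test_matches_brute_force_per_base_intersection(self):
        rng = np.random.default_rng(61)
        apexes = [("chr1", int(p)) for p in rng.integers(100, 9_900, 30)]
        regions = random_intervals(rng, 20, span=10_000, max_len=2_000)
        merged = threshold_low_cna(coverage(regions), hard_max=10**9)
        got = flank_and_intersect(apexes, merged, flank=65)
        window_mask = np.zeros(10_200, dtype=bool)
        for _, apex in apexes:
            window_mask[max(0, apex - 65) : apex + 66] = True
        region_mask = brute_intersect_mask(merged, "chr1", 10_200)
        expected = mask_to_intervals(window_mask & region_mask, "chr1")
        assert [(iv.chrom, iv.start, iv.end) for iv in got] == expected

    def test_intersect_intervals_outputs_sorted_half_open(self):
        a = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)]
        b = [GenomicInterval("chr1", 50, 250)]
        got = intersect_intervals(a, b)
        assert [(iv.start, iv.end) for iv in got] == [(50, 100), (200, 250)]


class TestCytosineFreeWindows:
    def test_enumerated_example(self):
        assert cytosine_free_windows("ATTAGGCATTA", 4) == [0, 1, 2, 7]

    def test_all_cytosine_sequence_is_empty(self):
        assert cytosine_free_windows("CCCCCC", 3) == []

    def test_window_longer_than_sequence(self):
        assert cytosine_free_windows("ATG", 10) == []

    def test_n_disqualifies_a_window(self):
        assert cytosine_free_windows("ATNAT", 2) == [0, 3]

    @given(
        st.text(alphabet="ACGTN", min_size=1, max_size=300),
        st.integers(min_value=1, max_value=30),
    )
    def test_matches_brute_force_scan(self, seq, window):
        assert cytosine_free_windows(seq, window) == brute_cytosine_free(seq, window)

    def test_revcomp_helper(self):
        assert revcomp("ACGTN") == "NACGT"
        assert revcomp(revcomp("GATTACA")) == "GATTACA"


class TestBedIO:
    def test_bed_round_trip_sorted(self, tmp_path):
        intervals = [
            GenomicInterval("chr2", 5, 10),
            GenomicInterval("chr1", 100, 200),
        ]
        path = tmp_path / "x.bed"
        write_bed(intervals, path)
        loaded = read_bed(path)
        assert [(iv.chrom, iv.start, iv.end) for iv in loaded] == [
            ("chr1", 100, 200),
            ("chr2", 5, 10),
        ]

    def test_malformed_line_reports_location(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\n")
        with pytest.raises(ValueError, match="line 1"):
            read_bed(path)
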