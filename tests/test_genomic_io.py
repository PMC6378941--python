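"""Coordinate conventions, coverage and counting against naive oracles."""

import numpy as np
import pytest

from mdts.genomic_io import (CountMatrix, GenomicInterval, MappabilityTrack,
                             ReadFilterConfig, SampleAlignments,
                             compute_coverage, count_reads_in_bins,
                             count_spans_in_bins, coverage_from_spans,
                             gc_content, mean_mappability, read_bed,
                             write_bed)

from conftest import write_simple_bam


class TestGenomicInterval:
    def test_size_is_closed_interval_arithmetic(self):
        assert GenomicInterval("chr1", 10, 10).size == 1
        assert GenomicInterval("chr1", 1, 100).size == 100

    @pytest.mark.parametrize("start,end", [(0, 5), (-1, 2), (10, 9)])
    def test_invalid_coordinates_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_bed_round_trip_is_lossless(self, tmp_path):
        ivs = [GenomicInterval("chr1", 1, 1),
               GenomicInterval("chr1", 100, 2956),
               GenomicInterval("chr2", 7, 7)]
        path = tmp_path / "bins.bed"
        write_bed(ivs, path)
        assert read_bed(path) == ivs

    def test_overlap_length(self):
        a = GenomicInterval("chr1", 10, 20)
        assert a.overlap_length(GenomicInterval("chr1", 20, 30)) == 1
        assert a.overlap_length(GenomicInterval("chr1", 21, 30)) == 0
        assert a.overlap_length(GenomicInterval("chr2", 10, 20)) == 0


class TestCoverage:
    def test_region_with_no_reads_is_all_zero(self, tmp_path):
        bam = write_simple_bam(tmp_path / "a.bam", {"chr1": 10_000}, [])
        cov = compute_coverage(SampleAlignments("a", bam),
                               GenomicInterval("chr1", 1, 500))
        assert cov.depth.shape == (500,)
        assert not cov.depth.any()

    def test_single_read_covers_exactly_its_span(self, tmp_path):
        bam = write_simple_bam(tmp_path / "a.bam", {"chr1": 10_000},
                               [("chr1", 201, 100)])
        cov = compute_coverage(SampleAlignments("a", bam),
                               GenomicInterval("chr1", 1, 1000))
        assert cov.depth.sum() == 100
        assert (cov.depth[200:300] == 1).all()
        assert cov.depth[199] == 0 and cov.depth[300] == 0

    def test_overlapping_reads_match_interval_stabbing_oracle(self, tmp_path):
        reads = [("chr1", s, ln) for s, ln in
                 [(100, 100), (150, 100), (150, 50), (199, 100),
                  (240, 100), (240, 100), (330, 10)]]
        bam = write_simple_bam(tmp_path / "a.bam", {"chr1": 10_000}, reads)
        region = GenomicInterval("chr1", 50, 450)
        cov = compute_coverage(SampleAlignments("a", bam), region)
        oracle = np.zeros(region.size, dtype=int)
        for base_index, base in enumerate(range(region.start, region.end + 1)):
            oracle[base_index] = sum(
                1 for _, s, ln in reads if s <= base <= s + ln - 1)
        np.testing.assert_array_equal(cov.depth, oracle)

    def test_filters_drop_low_mapq_and_duplicates(self, tmp_path):
        reads = [("chr1", 100, 100, 0, 0),      # MAPQ 0
                 ("chr1", 100, 100, 60, 0x400),  # duplicate
                 ("chr1", 100, 100, 60, 0x100),  # secondary
                 ("chr1", 100, 100, 60, 0)]      # retained
        bam = write_simple_bam(tmp_path / "a.bam", {"chr1": 10_000}, reads)
        cov = compute_coverage(SampleAlignments("a", bam),
                               GenomicInterval("chr1", 100, 199))
        assert (cov.depth == 1).all()

    def test_unknown_chromosome_warns_and_returns_zero(self, tmp_path):
        bam = write_simple_bam(tmp_path / "a.bam", {"chr1": 10_000}, [])
        with pytest.warns(UserWarning, match="absent"):
            cov = compute_coverage(SampleAlignments("a", bam),
                                   GenomicInterval("chrZ", 1, 100))
        assert not cov.depth.any()

    def test_missing_index_is_hard_error_naming_file(self, tmp_path):
        bam = write_simple_bam(tmp_path / "a.bam", {"chr1": 10_000}, [])
        (tmp_path / "a.bam.bai").unlink()
        with pytest.raises(FileNotFoundError, match="a.bam"):
            compute_coverage(SampleAlignments("a", bam),
                             GenomicInterval("chr1", 1, 100))


class TestCounting:
    def test_empty_alignments_count_zero(self, tmp_path):
        bam = write_simple_bam(tmp_path / "a.bam", {"chr1": 10_000}, [])
        bins = [GenomicInterval("chr1", 1, 100),
                GenomicInterval("chr1", 101, 200)]
        assert count_reads_in_bins(SampleAlignments("a", bam), bins).sum() == 0

    def test_boundary_read_counts_in_both_bins(self, tmp_path):
        bam = write_simple_bam(tmp_path / "a.bam", {"chr1": 10_000},
                               [("chr1", 151, 100)])
        bins = [GenomicInterval("chr1", 1, 200),
                GenomicInterval("chr1", 201, 400)]
        counts = count_reads_in_bins(SampleAlignments("a", bam), bins)
        np.testing.assert_array_equal(counts, [1, 1])

    def test_contained_reads_count_once(self, tmp_path):
        reads = [("chr1", 1001 + k, 100) for k in range(160)]
        bam = write_simple_bam(tmp_path / "a.bam", {"chr1": 10_000}, reads)
        bins = [GenomicInterval("chr1", 1001, 1400)]
        assert count_reads_in_bins(SampleAlignments("a", bam), bins)[0] == 160

    def test_overlapping_bins_rejected(self, tmp_path):
        bam = write_simple_bam(tmp_path / "a.bam", {"chr1": 10_000}, [])
        bins = [GenomicInterval("chr1", 1, 200),
                GenomicInterval("chr1", 150, 400)]
        with pytest.raises(ValueError, match="overlap"):
            count_reads_in_bins(SampleAlignments("a", bam), bins)

    def test_span_counting_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_reads = rng.integers(0, 200)
            starts = rng.integers(1, 5000, n_reads)
            ends = starts + rng.integers(1, 300, n_reads) - 1
            edges = np.sort(rng.choice(np.arange(1, 5500), 8, replace=False))
            bins = [GenomicInterval("chr1", int(a), int(b - 1))
                    for a, b in zip(edges[:-1], edges[1:])]
            got = count_spans_in_bins(starts, ends, bins)
            oracle = [sum(1 for s, e in zip(starts, ends)
                          if s <= b.end and e >= b.start) for b in bins]
            np.testing.assert_array_equal(got, oracle)

    def test_midpoint_mode_assigns_boundary_read_once(self, tmp_path):
        bam = write_simple_bam(tmp_path / "a.bam", {"chr1": 10_000},
                               [("chr1", 151, 100)])  # midpoint at base 200
        bins = [GenomicInterval("chr1", 1, 200),
                GenomicInterval("chr1", 201, 400)]
        counts = count_reads_in_bins(SampleAlignments("a", bam), bins,
                                     mode="midpoint")
        np.testing.assert_array_equal(counts, [1, 0])
        assert counts.sum() == 1

    def test_midpoint_mode_matches_brute_force(self):
        rng = np.random.default_rng(17)
        starts = rng.integers(1, 5000, 150)
        ends = starts + rng.integers(1, 300, 150) - 1
        edges = np.sort(rng.choice(np.arange(1, 5500), 8, replace=False))
        bins = [GenomicInterval("chr1", int(a), int(b - 1))
                for a, b in zip(edges[:-1], edges[1:])]
        got = count_spans_in_bins(starts, ends, bins, mode="midpoint")
        oracle = [sum(1 for s, e in zip(starts, ends)
                      if b.start <= (s + e) // 2 <= b.end) for b in bins]
        np.testing.assert_array_equal(got, oracle)

    def test_coverage_sum_equals_reads_times_length_when_contained(self,
                                                                   tmp_path):
        reads = [("chr1", 500 + 13 * k, 100) for k in range(20)]
        bam = write_simple_bam(tmp_path / "a.bam", {"chr1": 10_000}, reads)
        cov = compute_coverage(SampleAlignments("a", bam),
                               GenomicInterval("chr1", 1, 5000))
        assert cov.depth.sum() == 20 * 100


class TestGCAndMappability:
    @pytest.mark.parametrize("seq,expected", [
        ("GGCC", 1.0), ("ATAT", 0.0), ("ACGTN", 0.5)])
    def test_gc_content(self, seq, expected):
        fasta = {"chr1": seq}
        iv = GenomicInterval("chr1", 1, len(seq))
        assert gc_content(fasta, iv) == pytest.approx(expected)

    def test_all_n_sequence_is_undefined(self):
        assert np.isnan(gc_content({"chr1": "NNNN"},
                                   GenomicInterval("chr1", 1, 4)))

    def test_absent_chromosome_is_hard_error(self):
        with pytest.raises(KeyError):
            gc_content({"chr1": "ACGT"}, GenomicInterval("chr2", 1, 4))

    def test_constant_track(self):
        track = MappabilityTrack.constant(1.0)
        assert mean_mappability(track, GenomicInterval("chr1", 5, 50)) == 1.0

    def test_half_covered_bin_is_half(self):
        track = MappabilityTrack([GenomicInterval("chr1", 1, 50)], [1.0])
        assert mean_mappability(
            track, GenomicInterval("chr1", 1, 100)) == pytest.approx(0.5)

    def test_uncovered_bin_is_zero(self):
        track = MappabilityTrack([GenomicInterval("chr1", 1, 50)], [1.0])
        assert mean_mappability(track, GenomicInterval("chr1", 200, 300)) == 0.0

    def test_length_weighting(self):
        track = MappabilityTrack([GenomicInterval("chr1", 1, 30),
                                  GenomicInterval("chr1", 31, 40)],
                                 [1.0, 0.5])
        got = mean_mappability(track, GenomicInterval("chr1", 1, 40))
        assert got == pytest.approx((30 * 1.0 + 10 * 0.5) / 40)


class TestCountMatrix:
    def test_tsv_round_trip(self, tmp_path):
        bins = [GenomicInterval("chr1", 1, 100),
                GenomicInterval("chr1", 101, 250)]
        cm = CountMatrix(bins, ["s1", "s2"], np.array([[5, 7], [0, 3]]))
        path = tmp_path / "counts.tsv"
        cm.to_tsv(path)
        back = CountMatrix.from_tsv(path)
        assert back.samples == ["s1", "s2"]
        assert back.intervals() == bins
        np.testing.assert_array_equal(back.counts, cm.counts)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix([GenomicInterval("chr1", 1, 10)], ["s"],
                        np.array([[-1]]))
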