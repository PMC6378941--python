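"""Synthetic data generator: reads, spike-ins, scoring, determinism."""

import numpy as np
import pysam
import pytest

from mdts.binning import BinningConfig
from mdts.calling import DeNovoCall
from mdts.genomic_io import GenomicInterval, count_spans_in_bins
from mdts.simulation import (SpikeTruth, build_toy_genome,
                             build_bins_from_cohort, count_readset,
                             covered_fraction, generate_cohort,
                             make_capture_profile, score_calls,
                             simulate_trio_reads, spike_deletion,
                             spike_deletion_bam, write_readset_bam)
from mdts.trio_stats import Trio


class TestToyGenome:
    def test_deterministic_under_seed(self):
        a = build_toy_genome(3, n_regions=4, n_chroms=2,
                             chrom_length=500_000,
                             region_size_range=(7_000, 11_000))
        b = build_toy_genome(3, n_regions=4, n_chroms=2,
                             chrom_length=500_000,
                             region_size_range=(7_000, 11_000))
        assert a.regions == b.regions
        for c in a.seqs:
            np.testing.assert_array_equal(a.seqs[c], b.seqs[c])

    def test_regions_disjoint_and_sorted(self, small_genome):
        regs = small_genome.regions
        assert regs == sorted(regs)
        for x, y in zip(regs, regs[1:]):
            assert not x.overlaps(y)

    def test_gc_fraction_matches_sequence(self, small_genome):
        r = small_genome.regions[0]
        iv = GenomicInterval(r.chrom, r.start, r.start + 999)
        seq = str(small_genome[iv.chrom][iv.start - 1:iv.end])
        expected = (seq.count("G") + seq.count("C")) / 1000
        assert small_genome.gc_fraction(iv.chrom, iv.start, iv.end) == \
            pytest.approx(expected)

    def test_fasta_round_trip(self, small_genome, tmp_path):
        import pyfaidx
        path = tmp_path / "ref.fa"
        small_genome.write_fasta(path)
        fa = pyfaidx.Fasta(str(path))
        r = small_genome.regions[0]
        assert str(fa[r.chrom][r.start - 1:r.start + 49]) == \
            str(small_genome[r.chrom][r.start - 1:r.start + 49])


class TestReadSimulation:
    def test_same_seed_identical_reads(self, small_profile):
        trio = Trio("fam", "o", "f", "m")
        a = simulate_trio_reads(small_profile, trio, rng_seed=9)
        b = simulate_trio_reads(small_profile, trio, rng_seed=9)
        for sid in a:
            for chrom in a[sid].chroms():
                np.testing.assert_array_equal(a[sid].spans(chrom)[0],
                                              b[sid].spans(chrom)[0])

    def test_median_bin_count_hits_target(self, small_profile):
        rng = np.random.default_rng(10)
        cohort = generate_cohort(small_profile, 9, rng)
        bins = build_bins_from_cohort(cohort, BinningConfig(rng_seed=1))
        counts = np.column_stack(
            [count_readset(cohort.readsets[s], bins)
             for s in cohort.samples])
        med = np.median(counts)
        assert abs(med - 160) / 160 < 0.10

    def test_bam_emission_is_sorted_indexed_and_complete(self, small_genome,
                                                         small_profile,
                                                         tmp_path):
        trio = Trio("fam", "o", "f", "m")
        paths = simulate_trio_reads(small_profile, trio, rng_seed=11,
                                    outdir=str(tmp_path))
        with pysam.AlignmentFile(paths["o"]) as af:
            assert af.has_index()
            n = af.count(until_eof=False)  # requires index
        rs = simulate_trio_reads(small_profile, trio, rng_seed=11)["o"]
        assert n == rs.n_reads()


class TestSpike:
    def _readset(self, profile, seed=12):
        return simulate_trio_reads(profile, Trio("f", "o", "fa", "mo"),
                                   rng_seed=seed)["o"]

    def test_probability_zero_is_identity(self, small_profile):
        rs = self._readset(small_profile)
        iv = small_profile.regions[0]
        out = spike_deletion(rs, iv, 0.0, np.random.default_rng(0))
        for chrom in rs.chroms():
            np.testing.assert_array_equal(out.spans(chrom)[0],
                                          rs.spans(chrom)[0])

    def test_probability_one_removes_all_overlapping(self, small_profile):
        rs = self._readset(small_profile)
        r = small_profile.regions[0]
        iv = GenomicInterval(r.chrom, r.start + 1000, r.start + 3000)
        out = spike_deletion(rs, iv, 1.0, np.random.default_rng(0))
        starts, ends = out.spans(iv.chrom)
        assert not np.any((starts <= iv.end) & (ends >= iv.start))

    def test_half_drop_within_binomial_bounds(self, small_profile):
        rs = self._readset(small_profile)
        r = small_profile.regions[0]
        iv = GenomicInterval(r.chrom, r.start + 1000, r.start + 4000)
        starts, ends = rs.spans(iv.chrom)
        n_before = int(np.sum((starts <= iv.end) & (ends >= iv.start)))
        out = spike_deletion(rs, iv, 0.5, np.random.default_rng(1))
        s2, e2 = out.spans(iv.chrom)
        n_after = int(np.sum((s2 <= iv.end) & (e2 >= iv.start)))
        # 99% binomial bounds around n/2
        half, spread = n_before / 2, 2.58 * np.sqrt(n_before) / 2
        assert half - spread <= n_after <= half + spread

    def test_mean_bin_count_roughly_halves(self, small_profile):
        rs = self._readset(small_profile)
        r = small_profile.regions[1]
        iv = GenomicInterval(r.chrom, r.start + 2000, r.start + 6000)
        bins = [GenomicInterval(r.chrom, s, s + 199)
                for s in range(iv.start, iv.end - 199, 200)]
        before = count_spans_in_bins(*rs.spans(r.chrom), bins)
        out = spike_deletion(rs, iv, 0.5, np.random.default_rng(2))
        after = count_spans_in_bins(*out.spans(r.chrom), bins)
        ratio = after.sum() / before.sum()
        assert 0.45 < ratio < 0.55

    def test_reads_outside_interval_untouched(self, small_profile):
        rs = self._readset(small_profile)
        r0, r1 = small_profile.regions[0], small_profile.regions[1]
        iv = GenomicInterval(r0.chrom, r0.start, r0.end)
        out = spike_deletion(rs, iv, 1.0, np.random.default_rng(3))
        if r1.chrom != r0.chrom:
            np.testing.assert_array_equal(out.spans(r1.chrom)[0],
                                          rs.spans(r1.chrom)[0])

    def test_bam_spike_probability_one(self, small_genome, small_profile,
                                       tmp_path):
        rs = self._readset(small_profile)
        src = str(tmp_path / "in.bam")
        dst = str(tmp_path / "out.bam")
        write_readset_bam(rs, small_genome, src)
        r = small_profile.regions[0]
        iv = GenomicInterval(r.chrom, r.start + 500, r.start + 2500)
        spike_deletion_bam(src, dst, iv, 1.0, rng_seed=4)
        with pysam.AlignmentFile(dst) as af:
            hits = list(af.fetch(iv.chrom, iv.start - 1, iv.end))
        assert hits == []


class TestScoring:
    def _call(self, chrom, start, end, status="reported"):
        return DeNovoCall("fam", GenomicInterval(chrom, start, end), 3,
                          -0.9, 0, status)

    def _truth(self, chrom, start, end, kind="de_novo"):
        return SpikeTruth("fam", GenomicInterval(chrom, start, end), kind)

    def test_thirty_percent_coverage_detected_at_quarter_threshold(self):
        truth = [self._truth("chr1", 1000, 1999)]
        calls = [self._call("chr1", 1000, 1299)]
        assert score_calls(calls, truth, 0.25).detected[truth[0]]

    def test_ten_percent_only_detected_at_any_overlap(self):
        truth = [self._truth("chr1", 1000, 1999)]
        calls = [self._call("chr1", 1000, 1099)]
        assert not score_calls(calls, truth, 0.25).detected[truth[0]]
        assert score_calls(calls, truth, 0.0).detected[truth[0]]

    def test_no_calls_no_detections_no_fps(self):
        truth = [self._truth("chr1", 1000, 1999)]
        frag = score_calls([], truth, 0.25)
        assert not any(frag.detected.values())
        assert frag.false_positives == []

    def test_suppressed_calls_do_not_count(self):
        truth = [self._truth("chr1", 1000, 1999)]
        calls = [self._call("chr1", 1000, 1999, status="suppressed")]
        assert not score_calls(calls, truth, 0.25).detected[truth[0]]

    def test_unmatched_call_is_fp_and_inherited_match_recorded(self):
        truth = [self._truth("chr1", 1000, 1999, "de_novo"),
                 self._truth("chr1", 5000, 5999, "inherited")]
        calls = [self._call("chr1", 5000, 5999),
                 self._call("chr1", 9000, 9999)]
        frag = score_calls(calls, truth, 0.25)
        assert len(frag.false_positives) == 2
        assert frag.fp_matched_inherited == [True, False]
        assert frag.detected[truth[1]]  # inherited event was "called de novo"

    def test_covered_fraction_matches_per_base_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            t = GenomicInterval("chr1", 1000, 1000 + int(rng.integers(50, 500)))
            calls = []
            for _ in range(rng.integers(0, 5)):
                s = int(rng.integers(800, 1700))
                calls.append(GenomicInterval("chr1", s,
                                             s + int(rng.integers(10, 400))))
            got = covered_fraction(t, calls)
            covered = set()
            for c in calls:
                covered.update(range(max(c.start, t.start),
                                     min(c.end, t.end) + 1))
            assert got == pytest.approx(len(covered) / t.size)
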