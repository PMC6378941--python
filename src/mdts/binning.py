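"""Coverage-adaptive bin construction.

Bins are defined empirically from the data rather than from probe design
coordinates: a random subsample of study samples defines *proto-regions*
(maximal runs of bases where at least one subsampled sample reaches a
depth floor), and each proto-region is then partitioned left-to-right
into the smallest windows whose median read count across the subsample
reaches a target (default 160 reads).  High-coverage loci therefore get
narrow bins and poorly captured loci get wide ones.

The 160-read default puts the copy-neutral state more than six Poisson
standard deviations away from a heterozygous single-bin deletion
(see :func:`separation_sd`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import (CoverageVector, GenomicInterval, MappabilityTrack,
                         gc_content, mean_mappability)


@dataclass(frozen=True)
class BinningConfig:
    n_subsample: int = 25
    proto_min_depth: int = 10
    min_median_reads: int = 160
    min_mappability: float = 0.75
    gc_range: tuple[float, float] = (0.15, 0.85)
    rng_seed: int = 137

    def __post_init__(self) -> None:
        if self.proto_min_depth < 1 or self.min_median_reads < 1:
            raise ValueError("depth/read thresholds must be >= 1")
        lo, hi = self.gc_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("gc_range bounds must satisfy 0 <= lo <= hi <= 1")


@dataclass
class Bin:
    """A coverage-adaptive bin with its QC annotations."""

    interval: GenomicInterval
    gc: float = float("nan")
    mappability: float = float("nan")
    qc_pass: bool = True
    variability_flag: bool = False  # set later, from M scores


def subsample_samples(all_samples: Sequence[str],
                      config: BinningConfig) -> list[str]:
    """Uniform without-replacement subsample, reproducible under the seed.

    Returned in the input order.  If fewer samples than requested are
    available, all are used (with a warning).
    """
    if len(all_samples) <= config.n_subsample:
        if len(all_samples) < config.n_subsample:
            warnings.warn(
                f"only {len(all_samples)} samples available for binning "
                f"(requested {config.n_subsample}); using all")
        return list(all_samples)
    rng = np.random.default_rng(config.rng_seed)
    idx = rng.choice(len(all_samples), size=config.n_subsample, replace=False)
    return [all_samples[k] for k in sorted(idx)]


def find_proto_regions(coverages: Sequence[CoverageVector],
                       config: BinningConfig) -> list[GenomicInterval]:
    """Maximal runs where the across-sample max depth is >= the floor.

    All coverage vectors must share one chromosome and origin (one vector
    per subsampled sample over a common window).
    """
    if not coverages:
        return []
    chrom = coverages[0].chrom
    origin = coverages[0].origin
    for cv in coverages:
        if cv.chrom != chrom or cv.origin != origin:
            raise ValueError("coverage vectors are not on a common frame")
    depth = np.vstack([cv.depth for cv in coverages])
    hot = depth.max(axis=0) >= config.proto_min_depth
    return _runs_to_intervals(hot, chrom, origin)


def _runs_to_intervals(mask: np.ndarray, chrom: str,
                       origin: int) -> list[GenomicInterval]:
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return [GenomicInterval(chrom, origin + s, origin + e)
            for s, e in zip(starts, ends)]


def partition_proto_region(
        region: GenomicInterval,
        read_spans: Mapping[str, tuple[np.ndarray, np.ndarray]],
        config: BinningConfig) -> list[GenomicInterval]:
    """Partition one proto-region into bins of >= the target median reads.

    The scan grows the current bin base by base and closes it at the
    first base where the median (across the subsampled samples) number
    of reads overlapping the growing window reaches
    ``config.min_median_reads``.  Because each sample's overlap count is
    non-decreasing in the window end, so is the median, and the closing
    base can be found by bisection — the result is identical to the
    per-base scan.

    Trailing bases that never reach the target are merged into the last
    closed bin; a proto-region that never reaches the target at all
    becomes a single bin (retained, subject to QC).

    ``read_spans`` maps sample id -> (starts, ends), the 1-based closed
    aligned spans on the proto-region's chromosome.  The median over
    samples is the lower median for an even number of samples.
    """
    samples = list(read_spans)
    if not samples:
        return [region]
    k_med = (len(samples) - 1) // 2  # lower median
    # precompute, per sample, #(starts <= base) and #(ends < base) for
    # every base of the region: the overlap count for window [a, b] is
    # then a pair of table lookups
    bases = np.arange(region.start, region.end + 1, dtype=np.int64)
    n_start_le = np.empty((len(samples), bases.size), dtype=np.int64)
    n_end_lt = np.empty((len(samples), bases.size), dtype=np.int64)
    for si, s in enumerate(samples):
        ss = np.sort(np.asarray(read_spans[s][0], dtype=np.int64))
        es = np.sort(np.asarray(read_spans[s][1], dtype=np.int64))
        n_start_le[si] = np.searchsorted(ss, bases, side="right")
        n_end_lt[si] = np.searchsorted(es, bases - 1, side="right")

    def median_overlap(a: int, b: int) -> int:
        counts = n_start_le[:, b - region.start] - n_end_lt[:, a - region.start]
        return int(np.partition(counts, k_med)[k_med])

    bounds: list[tuple[int, int]] = []
    a = region.start
    target = config.min_median_reads
    while a <= region.end:
        if median_overlap(a, region.end) < target:
            # remainder cannot reach the target
            if bounds:
                bounds[-1] = (bounds[-1][0], region.end)
            else:
                bounds.append((a, region.end))
            break
        lo, hi = a, region.end  # invariant: median(a, hi) >= target
        while lo < hi:
            mid = (lo + hi) // 2
            if median_overlap(a, mid) >= target:
                hi = mid
            else:
                lo = mid + 1
        bounds.append((a, lo))
        a = lo + 1
    return [GenomicInterval(region.chrom, s, e) for s, e in bounds]


def apply_bin_qc(bins: Sequence[Bin], fasta,
                 mappability: MappabilityTrack,
                 config: BinningConfig) -> list[Bin]:
    """Annotate GC and mappability and set each bin's ``qc_pass``.

    A bin passes iff mappability >= the floor and GC inside the closed
    normal range; a bin whose GC is undefined (all-N sequence) fails.
    """
    out = []
    lo, hi = config.gc_range
    for b in bins:
        gc = gc_content(fasta, b.interval)
        mp = mean_mappability(mappability, b.interval)
        ok = bool((mp >= config.min_mappability) and (not math.isnan(gc))
                  and (lo <= gc <= hi))
        out.append(replace_bin(b, gc=gc, mappability=mp, qc_pass=ok))
    return out


def replace_bin(b: Bin, **kw) -> Bin:
    d = dict(interval=b.interval, gc=b.gc, mappability=b.mappability,
             qc_pass=b.qc_pass, variability_flag=b.variability_flag)
    d.update(kw)
    return Bin(**d)


def qc_passing(bins: Sequence[Bin]) -> list[Bin]:
    return [b for b in bins if b.qc_pass]


def separation_sd(min_median_reads: int) -> float:
    """Copy-neutral vs heterozygous-deletion separation, in Poisson SDs.

    Under a Poisson model with copy-neutral mean ``c`` reads per bin, a
    heterozygous deletion has mean ``c/2``; the distance between the two
    means is ``(c - c/2) / sqrt(c) = sqrt(c)/2`` copy-neutral standard
    deviations.  At the default c = 160 this exceeds 6.
    """
    c = min_median_reads
    if c <= 0:
        raise ValueError("min_median_reads must be positive")
    return (c - c / 2.0) / math.sqrt(c)


def build_bins(target_regions: Sequence[GenomicInterval],
               coverage_by_region: Mapping[int, Sequence[CoverageVector]],
               spans_by_region: Mapping[int, Mapping[str, tuple[np.ndarray, np.ndarray]]],
               fasta, mappability: MappabilityTrack,
               config: BinningConfig) -> list[Bin]:
    """Full binning pass over pre-fetched coverage and read spans.

    ``coverage_by_region[k]`` holds the subsampled samples' coverage over
    ``target_regions[k]``; ``spans_by_region[k]`` their read spans.
    Returns QC-annotated bins in genomic order (all bins, including QC
    failures, so callers can log exclusions).
    """
    bins: list[Bin] = []
    for k, region in enumerate(target_regions):
        protos = find_proto_regions(list(coverage_by_region[k]), config)
        for proto in protos:
            for iv in partition_proto_region(proto, spans_by_region[k], config):
                bins.append(Bin(interval=iv))
    return apply_bin_qc(bins, fasta, mappability, config)
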