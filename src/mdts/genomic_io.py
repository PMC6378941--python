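"""Genomic file I/O and read-depth primitives.

This module owns the coordinate convention of the whole package and the
low-level read-depth kernels everything else builds on:

* :class:`GenomicInterval` — 1-based, fully-closed intervals, so that
  ``size = end - start + 1``.  BED serialization converts to the 0-based
  half-open convention and back losslessly.
* per-base coverage and per-bin read counting, each available both for
  coordinate-sorted indexed BAM/SAM files (via :mod:`pysam`) and for plain
  arrays of aligned read spans (used by the simulator and by the
  brute-force oracles in the test-suite).
* GC content from an indexed FASTA and length-weighted mean mappability
  from a bedGraph-style interval track.

Counting rule: a retained read contributes one count to *every* bin its
aligned span overlaps by at least one base pair; mates of a pair are
counted independently.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully-closed genomic interval."""

    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.end and other.start <= self.end)

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.start and other.end <= self.end)


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a BED file (0-based half-open) into 1-based closed intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(GenomicInterval(f[0], int(f[1]) + 1, int(f[2])))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike,
              names: Sequence[str] | None = None) -> None:
    """Write intervals as BED (converting to 0-based half-open)."""
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            row = [iv.chrom, str(iv.start - 1), str(iv.end)]
            if names is not None:
                row.append(names[k])
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# mappability track
# ---------------------------------------------------------------------------

class MappabilityTrack:
    """Per-base mappability, stored as sorted interval runs per chromosome.

    Bases not covered by any interval contribute a value of 0 to averages.
    ``MappabilityTrack.constant(1.0)`` gives the download-free default in
    which every base is perfectly mappable.
    """

    def __init__(self, intervals: Sequence[GenomicInterval] = (),
                 values: Sequence[float] = (),
                 constant: float | None = None):
        if constant is not None and len(intervals):
            raise ValueError("give either intervals or a constant, not both")
        self._constant = constant
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        values = np.asarray(values, dtype=float)
        if len(intervals):
            if values.min(initial=0.0) < 0 or values.max(initial=0.0) > 1:
                raise ValueError("mappability values must lie in [0, 1]")
            chroms = {}
            for k, iv in enumerate(intervals):
                chroms.setdefault(iv.chrom, []).append(
                    (iv.start, iv.end, float(values[k])))
            for chrom, rows in chroms.items():
                rows.sort()
                s = np.array([r[0] for r in rows])
                e = np.array([r[1] for r in rows])
                v = np.array([r[2] for r in rows])
                if np.any(s[1:] <= e[:-1]):
                    raise ValueError(f"overlapping track intervals on {chrom}")
                self._by_chrom[chrom] = (s, e, v)

    @classmethod
    def constant(cls, value: float = 1.0) -> "MappabilityTrack":
        return cls(constant=value)

    @classmethod
    def from_bedgraph(cls, path: str | os.PathLike) -> "MappabilityTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
        ivs = [GenomicInterval(r.chrom, int(r.start) + 1, int(r.end))
               for r in df.itertuples()]
        return cls(ivs, df["value"].to_numpy())

    def mean(self, interval: GenomicInterval) -> float:
        """Length-weighted mean value over ``interval`` (absent bases = 0)."""
        if self._constant is not None:
            return self._constant
        if interval.chrom not in self._by_chrom:
            return 0.0
        s, e, v = self._by_chrom[interval.chrom]
        lo = max(0, np.searchsorted(e, interval.start) )
        total = 0.0
        for k in range(lo, len(s)):
            if s[k] > interval.end:
                break
            ov = min(e[k], interval.end) - max(s[k], interval.start) + 1
            if ov > 0:
                total += ov * v[k]
        return total / interval.size


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadFilterConfig:
    """Which reads are retained for coverage and counting.

    Defaults follow standard read-depth practice: primary alignments with
    MAPQ >= 1, no duplicates.
    """

    min_mapq: int = 1
    exclude_duplicates: bool = True
    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    exclude_unmapped: bool = True

    def keep(self, read: "pysam.AlignedSegment") -> bool:
        if self.exclude_unmapped and read.is_unmapped:
            return False
        if read.mapping_quality < self.min_mapq:
            return False
        if self.exclude_duplicates and read.is_duplicate:
            return False
        if self.exclude_secondary and read.is_secondary:
            return False
        if self.exclude_supplementary and read.is_supplementary:
            return False
        return True


@dataclass(frozen=True)
class SampleAlignments:
    """A sample's coordinate-sorted, indexed alignment file."""

    sample_id: str
    path: str

    def open(self) -> pysam.AlignmentFile:
        af = pysam.AlignmentFile(self.path)
        if not af.has_index():
            af.close()
            raise FileNotFoundError(
                f"alignment file {self.path!r} has no index; "
                "coordinate-sorted, indexed input is required")
        return af


@dataclass
class CoverageVector:
    """Per-base read depth over a window, 1-based origin."""

    chrom: str
    origin: int
    depth: np.ndarray  # non-negative integers

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.size and self.depth.min() < 0:
            raise ValueError("negative depth")


@dataclass
class CountMatrix:
    """Bins-by-samples integer read counts."""

    bins: list            # list of binning.Bin or GenomicInterval
    samples: list[str]
    counts: np.ndarray    # shape (n_bins, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.bins), len(self.samples)):
            raise ValueError("counts shape inconsistent with bins/samples")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("negative counts")

    def intervals(self) -> list[GenomicInterval]:
        return [_as_interval(b) for b in self.bins]

    def to_tsv(self, path: str | os.PathLike) -> None:
        ivs = self.intervals()
        df = pd.DataFrame({"chrom": [iv.chrom for iv in ivs],
                           "start": [iv.start for iv in ivs],
                           "end": [iv.end for iv in ivs]})
        for k, s in enumerate(self.samples):
            df[s] = self.counts[:, k]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t")
        samples = [c for c in df.columns if c not in ("chrom", "start", "end")]
        bins = [GenomicInterval(r.chrom, int(r.start), int(r.end))
                for r in df.itertuples()]
        return cls(bins, samples, df[samples].to_numpy(dtype=np.int64))


def _as_interval(b) -> GenomicInterval:
    return b if isinstance(b, GenomicInterval) else b.interval


# ---------------------------------------------------------------------------
# span-level kernels (shared by BAM readers, simulator and test oracles)
# ---------------------------------------------------------------------------

def coverage_from_spans(starts: np.ndarray, ends: np.ndarray,
                        region: GenomicInterval) -> np.ndarray:
    """Per-base depth over ``region`` from 1-based closed aligned spans."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    n = region.size
    diff = np.zeros(n + 1, dtype=np.int64)
    s = np.clip(starts - region.start, 0, n)
    e = np.clip(ends - region.start + 1, 0, n)
    keep = (ends >= region.start) & (starts <= region.end)
    np.add.at(diff, s[keep], 1)
    np.add.at(diff, e[keep], -1)
    return np.cumsum(diff[:-1])


def count_spans_in_bins(starts: np.ndarray, ends: np.ndarray,
                        bins: Sequence, mode: str = "overlap") -> np.ndarray:
    """Number of spans assigned to each bin.

    ``starts``/``ends`` are 1-based closed spans on a single chromosome;
    bins must be sorted and non-overlapping (spans need not be sorted).

    The default ``overlap`` mode counts a span in every bin it overlaps
    by >= 1 bp: the count is ``#(start <= bin.end) - #(end < bin.start)``.
    The alternative ``midpoint`` mode assigns each span to the single bin
    containing its midpoint (lower midpoint for even-length spans), so no
    read is ever counted twice.
    """
    ivs = [_as_interval(b) for b in bins]
    _check_bins_disjoint_sorted(ivs)
    bs = np.array([iv.start for iv in ivs], dtype=np.int64)
    be = np.array([iv.end for iv in ivs], dtype=np.int64)
    if mode == "overlap":
        ss = np.sort(np.asarray(starts, dtype=np.int64))
        es = np.sort(np.asarray(ends, dtype=np.int64))
        return (np.searchsorted(ss, be, side="right")
                - np.searchsorted(es, bs - 1, side="right"))
    if mode == "midpoint":
        mids = np.sort((np.asarray(starts, dtype=np.int64)
                        + np.asarray(ends, dtype=np.int64)) // 2)
        return (np.searchsorted(mids, be, side="right")
                - np.searchsorted(mids, bs - 1, side="right"))
    raise ValueError(f"unknown counting mode {mode!r}")


def _check_bins_disjoint_sorted(ivs: Sequence[GenomicInterval]) -> None:
    for a, b in zip(ivs, ivs[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            raise ValueError(
                f"bins overlap or are unsorted: {a} followed by {b}")


def fetch_read_spans(aln: SampleAlignments, region: GenomicInterval,
                     filters: ReadFilterConfig | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Aligned spans (1-based closed) of retained reads overlapping a region."""
    filters = filters or ReadFilterConfig()
    starts: list[int] = []
    ends: list[int] = []
    with aln.open() as af:
        if region.chrom not in af.references:
            warnings.warn(f"chromosome {region.chrom!r} absent from "
                          f"{aln.path}; returning no reads")
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        for read in af.fetch(region.chrom, region.start - 1, region.end):
            if not filters.keep(read):
                continue
            starts.append(read.reference_start + 1)
            ends.append(read.reference_end)  # 0-based exclusive == 1-based inclusive
    return (np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64))


# ---------------------------------------------------------------------------
# BAM-level operations
# ---------------------------------------------------------------------------

def compute_coverage(aln: SampleAlignments, region: GenomicInterval,
                     filters: ReadFilterConfig | None = None) -> CoverageVector:
    """Per-base depth of retained reads over ``region``."""
    starts, ends = fetch_read_spans(aln, region, filters)
    depth = coverage_from_spans(starts, ends, region)
    return CoverageVector(region.chrom, region.start, depth)


def count_reads_in_bins(aln: SampleAlignments, bins: Sequence,
                        filters: ReadFilterConfig | None = None,
                        mode: str = "overlap") -> np.ndarray:
    """One CountMatrix column: retained reads assigned to each bin.

    Bins must be sorted and non-overlapping.  In the default ``overlap``
    mode a read whose aligned span crosses a bin boundary contributes
    one count to each bin it touches; ``midpoint`` mode assigns it to
    the bin containing its midpoint only.
    """
    ivs = [_as_interval(b) for b in bins]
    _check_bins_disjoint_sorted(ivs)
    out = np.zeros(len(ivs), dtype=np.int64)
    # fetch per chromosome once, then count with the span kernel
    by_chrom: dict[str, list[int]] = {}
    for k, iv in enumerate(ivs):
        by_chrom.setdefault(iv.chrom, []).append(k)
    for chrom, idx in by_chrom.items():
        lo = min(ivs[k].start for k in idx)
        hi = max(ivs[k].end for k in idx)
        starts, ends = fetch_read_spans(aln, GenomicInterval(chrom, lo, hi),
                                        filters)
        sub = [ivs[k] for k in idx]
        out[np.asarray(idx)] = count_spans_in_bins(starts, ends, sub, mode)
    return out


def gc_content(fasta, interval: GenomicInterval) -> float:
    """(#G + #C) / (#non-N bases) over ``interval``; NaN if all bases are N.

    ``fasta`` is a ``pyfaidx.Fasta`` (or any mapping of chrom -> sliceable
    sequence).  An absent chromosome is a hard error.
    """
    if interval.chrom not in fasta:
        raise KeyError(f"chromosome {interval.chrom!r} absent from reference")
    seq = str(fasta[interval.chrom][interval.start - 1:interval.end]).upper()
    n_gc = seq.count("G") + seq.count("C")
    n_valid = len(seq) - seq.count("N")
    if n_valid == 0:
        return float("nan")
    return n_gc / n_valid


def mean_mappability(track: MappabilityTrack,
                     interval: GenomicInterval) -> float:
    """Length-weighted mean mappability of ``interval``; uncovered bases = 0."""
    return track.mean(interval)
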