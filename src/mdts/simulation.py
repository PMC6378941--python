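"""Synthetic trio capture-sequencing data and the spike-in benchmark.

The generator emulates paired-end 100 bp capture sequencing over a toy
genome with a handful of targeted regions: fragments are placed by a
Poisson process whose per-base intensity is a smooth, heterogeneous
capture profile, fragment lengths are Gaussian, a mild smooth GC bias
thins fragments, and each sample carries a log-normal depth scale to
mimic inter-sample variation.  Median per-bin coverage is calibrated to
the study-like ~66x so that bins targeting 160 median reads come out a
couple of hundred base pairs wide.

Deletions are spiked in by independently dropping reads that overlap a
chosen interval with probability 0.5 — in the proband only (de novo) or
in the proband and one parent (inherited).  The benchmark spikes 5 de
novo and 5 inherited deletions of sizes 250/500/1000/2000/4000 bp per
trio instance, runs the full pipeline, and scores detection by the
fraction of each truth interval covered by reported calls (thresholds:
any overlap, 25%, 50%).

What the generator does **not** emulate: sequencing errors, split reads,
probe-level capture chemistry, batch effects, or real CNP structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import binning as _binning
from . import normalization as _norm
from .binning import Bin, BinningConfig, apply_bin_qc, qc_passing, subsample_samples
from .calling import CallingConfig, DeNovoCall, call_de_novo, flag_variable_bins
from .genomic_io import (CoverageVector, GenomicInterval, count_spans_in_bins,
                         coverage_from_spans, MappabilityTrack)
from .normalization import MScoreMatrix
from .segmentation import CBSConfig, segment_md_track
from .trio_stats import Trio, compute_md_track, family_qc

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------

class _ChromView:
    """Minimal pyfaidx-like view over a coded sequence array."""

    def __init__(self, codes: np.ndarray):
        self._codes = codes

    def __getitem__(self, sl) -> "_ChromView":
        return _ChromView(self._codes[sl])

    def __str__(self) -> str:
        return _BASES[self._codes].tobytes().decode()

    def __len__(self) -> int:
        return self._codes.size


class ToyGenome:
    """A deterministic synthetic reference with targeted capture regions.

    Sequence composition drifts smoothly in GC along each chromosome so
    that bins span a realistic GC range.  Supports the small mapping
    protocol :func:`mdts.genomic_io.gc_content` expects, so it can stand
    in for a ``pyfaidx.Fasta``.
    """

    def __init__(self, seqs: dict[str, np.ndarray],
                 regions: list[GenomicInterval]):
        self.seqs = seqs
        self.regions = regions
        self._gc_cum = {c: np.concatenate(
            [[0], np.cumsum(((s == 1) | (s == 2)).astype(np.int32))])
            for c, s in seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seqs

    def __getitem__(self, chrom: str) -> _ChromView:
        return _ChromView(self.seqs[chrom])

    def chrom_length(self, chrom: str) -> int:
        return self.seqs[chrom].size

    def gc_fraction(self, chrom: str, start: int, end: int) -> float:
        """GC fraction of the 1-based closed [start, end]."""
        cum = self._gc_cum[chrom]
        return (cum[end] - cum[start - 1]) / (end - start + 1)

    def write_fasta(self, path, line_width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom, codes in self.seqs.items():
                fh.write(f">{chrom}\n")
                raw = _BASES[codes].tobytes().decode()
                for k in range(0, len(raw), line_width):
                    fh.write(raw[k:k + line_width] + "\n")


def build_toy_genome(seed: int = 137, n_regions: int = 13,
                     n_chroms: int = 4, chrom_length: int = 2_000_000,
                     region_size_range: tuple[int, int] = (8_000, 35_000),
                     ) -> ToyGenome:
    """Toy genome with ``n_regions`` disjoint capture regions.

    GC content follows a smoothed random walk around 0.45 per 1 kb
    block; regions are spread over the chromosomes with wide gaps.
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, np.ndarray] = {}
    block = 1000
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        n_blocks = chrom_length // block
        z = rng.normal(size=n_blocks)
        kernel = np.ones(15) / 15.0
        smooth = np.convolve(z, kernel, mode="same")
        gc_t = np.clip(0.45 + 0.35 * smooth, 0.22, 0.68)
        gc_per_base = np.repeat(gc_t, block)[:chrom_length]
        u = rng.random(chrom_length)
        is_gc = u < gc_per_base
        second = rng.random(chrom_length) < 0.5
        codes = np.where(is_gc, np.where(second, 1, 2),
                         np.where(second, 0, 3)).astype(np.uint8)
        seqs[chrom] = codes
    # place regions round-robin over chromosomes, far apart
    lo, hi = region_size_range
    sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_regions))
    sizes = sizes.astype(int)
    regions: list[GenomicInterval] = []
    per_chrom: dict[str, int] = {c: 100_000 for c in seqs}
    for k in range(n_regions):
        chrom = f"chr{k % n_chroms + 1}"
        start = per_chrom[chrom]
        end = start + sizes[k] - 1
        if end > chrom_length - 100_000:
            raise ValueError("chromosomes too short for requested regions")
        regions.append(GenomicInterval(chrom, start, end))
        per_chrom[chrom] = end + rng.integers(60_000, 120_000)
    regions.sort()
    return ToyGenome(seqs, regions)


# ---------------------------------------------------------------------------
# capture profile and read sets
# ---------------------------------------------------------------------------

def _default_gc_bias(gc: np.ndarray) -> np.ndarray:
    """Mild capture efficiency loss away from 45% GC (acceptance prob)."""
    return np.exp(-0.5 * ((gc - 0.45) / 0.25) ** 2)


@dataclass
class CaptureProfile:
    """Study-condition parameters for the read simulator.

    ``pair_rate`` is fragment pairs per base pair per unit depth scale
    and is calibrated so realized median per-bin coverage is about the
    study's 66x.  ``intensity`` holds one positive per-base array per
    region (mean ~1) expressing capture heterogeneity.
    """

    genome: ToyGenome
    intensity: list[np.ndarray]
    read_length: int = 100
    fragment_mean: float = 350.0
    fragment_sd: float = 60.0
    pair_rate: float = 0.355
    depth_sigma: float = 0.2
    gc_bias: Callable[[np.ndarray], np.ndarray] | None = _default_gc_bias

    @property
    def regions(self) -> list[GenomicInterval]:
        return self.genome.regions


def make_capture_profile(genome: ToyGenome, seed: int = 137,
                         heterogeneity: float = 0.5,
                         **kwargs) -> CaptureProfile:
    """Smooth log-normal capture-intensity field per region."""
    rng = np.random.default_rng(seed)
    intensity = []
    for region in genome.regions:
        n_knots = max(4, region.size // 2000)
        z = np.convolve(rng.normal(size=n_knots + 8), np.ones(5) / 5.0,
                        mode="same")
        knots = np.linspace(0, region.size - 1, n_knots + 8)
        field_ = np.interp(np.arange(region.size), knots, z)
        arr = np.exp(heterogeneity * field_)
        intensity.append(arr / arr.mean())
    return CaptureProfile(genome=genome, intensity=intensity, **kwargs)


class ReadSet:
    """In-memory paired-end reads for one sample.

    Per chromosome: mate-1 starts, mate-2 starts (each mate spans
    ``read_length`` bases), a proper-pair flag per pair, and orphan
    single-read starts left behind by spike-in read dropping.
    """

    def __init__(self, read_length: int):
        self.read_length = read_length
        self.data: dict[str, dict[str, np.ndarray]] = {}

    def add_pairs(self, chrom: str, m1: np.ndarray, m2: np.ndarray,
                  proper: np.ndarray | None = None) -> None:
        if proper is None:
            proper = np.ones(m1.size, dtype=bool)
        d = self.data.setdefault(chrom, {
            "m1": np.empty(0, np.int64), "m2": np.empty(0, np.int64),
            "proper": np.empty(0, bool), "singles": np.empty(0, np.int64)})
        d["m1"] = np.concatenate([d["m1"], np.asarray(m1, np.int64)])
        d["m2"] = np.concatenate([d["m2"], np.asarray(m2, np.int64)])
        d["proper"] = np.concatenate([d["proper"], proper])

    def chroms(self) -> list[str]:
        return list(self.data)

    def spans(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """All read spans (1-based closed) on a chromosome."""
        if chrom not in self.data:
            e = np.empty(0, np.int64)
            return e, e
        d = self.data[chrom]
        starts = np.concatenate([d["m1"], d["m2"], d["singles"]])
        return starts, starts + self.read_length - 1

    def n_reads(self) -> int:
        return sum(2 * d["m1"].size + d["singles"].size
                   for d in self.data.values())

    def copy(self) -> "ReadSet":
        out = ReadSet(self.read_length)
        out.data = {c: {k: v.copy() for k, v in d.items()}
                    for c, d in self.data.items()}
        return out


def simulate_sample_reads(profile: CaptureProfile, depth_scale: float,
                          rng: np.random.Generator) -> ReadSet:
    """One sample's reads: Poisson fragment placement along the profile."""
    rs = ReadSet(profile.read_length)
    L = profile.read_length
    for region, inten in zip(profile.regions, profile.intensity):
        lam = profile.pair_rate * depth_scale * float(inten.sum())
        n = rng.poisson(lam)
        if n == 0:
            continue
        cum = np.cumsum(inten)
        u = rng.random(n) * cum[-1]
        offs = np.searchsorted(cum, u)
        frag = rng.normal(profile.fragment_mean, profile.fragment_sd, n)
        frag = np.maximum(frag, 2 * L + 10).astype(np.int64)
        # fragment midpoint at the sampled capture position
        f_start = region.start + offs - frag // 2
        chrom_len = profile.genome.chrom_length(region.chrom)
        f_start = np.clip(f_start, 1, chrom_len - frag)
        if profile.gc_bias is not None:
            cumgc = profile.genome._gc_cum[region.chrom]
            gc = (cumgc[f_start + frag - 1] - cumgc[f_start - 1]) / frag
            keep = rng.random(n) < profile.gc_bias(gc)
            f_start, frag = f_start[keep], frag[keep]
        m1 = f_start
        m2 = f_start + frag - L
        rs.add_pairs(region.chrom, m1, m2)
    for d in rs.data.values():
        order = np.argsort(d["m1"], kind="stable")
        d["m1"], d["m2"] = d["m1"][order], d["m2"][order]
        d["proper"] = d["proper"][order]
    return rs


def simulate_trio_reads(profile: CaptureProfile, trio: Trio,
                        rng_seed: int, outdir=None) -> dict:
    """Reads for the three members of a trio, deterministic under the seed.

    Returns ``{sample_id: ReadSet}``; if ``outdir`` is given, also
    writes one coordinate-sorted, indexed BAM per member (plus the toy
    reference FASTA) and returns ``{sample_id: path}`` instead.
    """
    rng = np.random.default_rng(rng_seed)
    readsets = {}
    for sid in trio.members:
        scale = float(rng.lognormal(mean=0.0, sigma=profile.depth_sigma))
        readsets[sid] = simulate_sample_reads(profile, scale, rng)
    if outdir is None:
        return readsets
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for sid, rs in readsets.items():
        path = os.path.join(outdir, f"{sid}.bam")
        write_readset_bam(rs, profile.genome, path)
        paths[sid] = path
    return paths


def write_readset_bam(rs: ReadSet, genome: ToyGenome, path: str) -> None:
    """Emit a coordinate-sorted, indexed BAM (sequence-less 100M records)."""
    import pysam
    chroms = list(genome.seqs)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": genome.chrom_length(c)} for c in chroms]}
    tid = {c: k for k, c in enumerate(chroms)}
    L = rs.read_length
    records = []
    pair_id = 0
    for chrom in rs.chroms():
        d = rs.data[chrom]
        for m1, m2, proper in zip(d["m1"], d["m2"], d["proper"]):
            pair_id += 1
            name = f"p{pair_id}"
            tlen = int(m2 + L - m1)
            records.append((tid[chrom], int(m1) - 1, name, 0x63 if proper
                            else 0x61, int(m2) - 1, tlen))
            records.append((tid[chrom], int(m2) - 1, name, 0x93 if proper
                            else 0x91, int(m1) - 1, -tlen))
        for s in d["singles"]:
            pair_id += 1
            records.append((tid[chrom], int(s) - 1, f"s{pair_id}", 0x0,
                            -1, 0))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for rtid, pos, name, flag, mpos, tlen in records:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = rtid
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = [(0, L)]
            if mpos >= 0:
                a.next_reference_id = rtid
                a.next_reference_start = mpos
                a.template_length = tlen
            bam.write(a)
    pysam.index(path)


def add_discordant_pairs(rs: ReadSet, interval: GenomicInterval, n: int,
                         rng: np.random.Generator, gap_sd: int = 200) -> None:
    """Inject long-insert pairs straddling ``interval`` (deletion signature)."""
    L = rs.read_length
    m1 = interval.start - L - rng.integers(0, 3 * gap_sd, size=n)
    m2 = interval.end + 1 + rng.integers(0, 3 * gap_sd, size=n)
    rs.add_pairs(interval.chrom, m1.astype(np.int64), m2.astype(np.int64),
                 proper=np.zeros(n, dtype=bool))


# ---------------------------------------------------------------------------
# spike-ins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeTruth:
    family_id: str
    interval: GenomicInterval
    kind: str                  # "de_novo" | "inherited"
    carrier_parent: str = "none"  # "father" | "mother" | "none"
    drop_probability: float = 0.5


def spike_deletion(rs: ReadSet, interval: GenomicInterval,
                   drop_probability: float,
                   rng: np.random.Generator) -> ReadSet:
    """Drop reads overlapping ``interval`` independently with probability p.

    Mates are treated as separate reads: a mate that does not overlap
    the interval always survives, possibly as an orphan single read.
    """
    if not (0.0 <= drop_probability <= 1.0):
        raise ValueError("drop_probability must be in [0, 1]")
    out = rs.copy()
    if interval.chrom not in out.data:
        return out
    d = out.data[interval.chrom]
    L = rs.read_length

    def overlapping(starts: np.ndarray) -> np.ndarray:
        return (starts <= interval.end) & (starts + L - 1 >= interval.start)

    drop1 = overlapping(d["m1"]) & (rng.random(d["m1"].size) < drop_probability)
    drop2 = overlapping(d["m2"]) & (rng.random(d["m2"].size) < drop_probability)
    keep_pair = ~drop1 & ~drop2
    orphan = np.concatenate([d["m1"][~drop1 & drop2],
                             d["m2"][drop1 & ~drop2]])
    drop_s = overlapping(d["singles"]) & \
        (rng.random(d["singles"].size) < drop_probability)
    d["singles"] = np.sort(np.concatenate([d["singles"][~drop_s], orphan]))
    d["m1"] = d["m1"][keep_pair]
    d["m2"] = d["m2"][keep_pair]
    d["proper"] = d["proper"][keep_pair]
    return out


def spike_deletion_bam(in_path: str, out_path: str,
                       interval: GenomicInterval, drop_probability: float,
                       rng_seed: int) -> None:
    """BAM-to-BAM spike-in: drop overlapping reads independently with p."""
    import pysam
    rng = np.random.default_rng(rng_seed)
    with pysam.AlignmentFile(in_path) as src, \
            pysam.AlignmentFile(out_path, "wb", template=src) as dst:
        for read in src.fetch(until_eof=True):
            if (not read.is_unmapped
                    and read.reference_name == interval.chrom
                    and read.reference_start + 1 <= interval.end
                    and read.reference_end >= interval.start
                    and rng.random() < drop_probability):
                continue
            dst.write(read)
    pysam.index(out_path)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def covered_fraction(truth: GenomicInterval,
                     calls: Sequence[GenomicInterval]) -> float:
    """Fraction of ``truth`` covered by the union of ``calls``."""
    mask = np.zeros(truth.size, dtype=bool)
    for c in calls:
        if c.chrom != truth.chrom:
            continue
        lo = max(c.start, truth.start) - truth.start
        hi = min(c.end, truth.end) - truth.start
        if hi >= lo:
            mask[lo:hi + 1] = True
    return float(mask.mean())


@dataclass
class ScoreFragment:
    threshold: float                       # 0.0 means "any overlap"
    detected: dict                         # SpikeTruth -> bool
    false_positives: list[DeNovoCall]
    fp_matched_inherited: list[bool]


def score_calls(calls: Sequence[DeNovoCall], truth: Sequence[SpikeTruth],
                threshold: float = 0.25) -> ScoreFragment:
    """Overlap-based benchmark scoring.

    A truth deletion counts as called when the fraction of its length
    covered by reported calls reaches ``threshold`` (or is positive,
    for threshold 0 = any overlap).  A reported call that does not cover
    at least the threshold fraction of some de novo truth is an
    additional false positive; whether it instead matches an inherited
    truth is recorded separately.
    """
    rep = [c for c in calls if c.status == "reported"]
    call_ivs = [c.interval for c in rep]

    def hit(frac: float) -> bool:
        return frac > 0.0 if threshold == 0.0 else frac >= threshold

    detected = {t: hit(covered_fraction(t.interval, call_ivs)) for t in truth}
    fps: list[DeNovoCall] = []
    fp_inh: list[bool] = []
    dn = [t for t in truth if t.kind == "de_novo"]
    inh = [t for t in truth if t.kind == "inherited"]
    for c in rep:
        if any(hit(covered_fraction(t.interval, [c.interval])) for t in dn):
            continue
        fps.append(c)
        fp_inh.append(any(hit(covered_fraction(t.interval, [c.interval]))
                          for t in inh))
    return ScoreFragment(threshold, detected, fps, fp_inh)


# ---------------------------------------------------------------------------
# cohort and benchmark
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    profile: CaptureProfile
    trios: list[Trio]
    readsets: dict[str, ReadSet]
    depth_scales: dict[str, float]

    @property
    def samples(self) -> list[str]:
        return [sid for t in self.trios for sid in t.members]


def generate_cohort(profile: CaptureProfile, n_trios: int,
                    rng: np.random.Generator) -> SyntheticCohort:
    trios = [Trio(f"F{k:04d}", f"F{k:04d}-O", f"F{k:04d}-F", f"F{k:04d}-M")
             for k in range(1, n_trios + 1)]
    readsets: dict[str, ReadSet] = {}
    scales: dict[str, float] = {}
    for t in trios:
        for sid in t.members:
            scale = float(rng.lognormal(0.0, profile.depth_sigma))
            scales[sid] = scale
            readsets[sid] = simulate_sample_reads(profile, scale, rng)
    return SyntheticCohort(profile, trios, readsets, scales)


def count_readset(rs: ReadSet, bins: Sequence[Bin]) -> np.ndarray:
    """Reads overlapping each bin (bins sorted, possibly multi-chromosome)."""
    from .genomic_io import _as_interval
    out = np.zeros(len(bins), dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for k, b in enumerate(bins):
        by_chrom.setdefault(_as_interval(b).chrom, []).append(k)
    for chrom, idx in by_chrom.items():
        starts, ends = rs.spans(chrom)
        out[np.asarray(idx)] = count_spans_in_bins(
            starts, ends, [bins[k] for k in idx])
    return out


def build_bins_from_cohort(cohort: SyntheticCohort,
                           config: BinningConfig) -> list[Bin]:
    """Coverage-adaptive bins from a subsample of the synthetic cohort."""
    sub = subsample_samples(cohort.samples, config)
    genome = cohort.profile.genome
    bins: list[Bin] = []
    for region in cohort.profile.regions:
        covs = []
        spans = {}
        for sid in sub:
            starts, ends = cohort.readsets[sid].spans(region.chrom)
            covs.append(CoverageVector(
                region.chrom, region.start,
                coverage_from_spans(starts, ends, region)))
            spans[sid] = (starts, ends)
        for proto in _binning.find_proto_regions(covs, config):
            for iv in _binning.partition_proto_region(proto, spans, config):
                bins.append(Bin(interval=iv))
    return apply_bin_qc(bins, genome, MappabilityTrack.constant(1.0), config)


def _sample_spike_intervals(regions: Sequence[GenomicInterval],
                            sizes: Sequence[int],
                            rng: np.random.Generator,
                            margin: int = 300,
                            max_tries: int = 1000) -> list[GenomicInterval]:
    """Disjoint random intervals of the given sizes inside the regions.

    A small margin keeps distinct spikes out of the same bin.  Raises if
    placement fails (caller redraws the replicate).
    """
    sizes = list(sizes)
    weights = np.array([r.size for r in regions], dtype=float)
    weights /= weights.sum()
    chosen: list[GenomicInterval] = []
    for size in sizes:
        for _ in range(max_tries):
            r = regions[rng.choice(len(regions), p=weights)]
            if r.size <= size + 2:
                continue
            start = int(rng.integers(r.start, r.end - size + 2))
            iv = GenomicInterval(r.chrom, start, start + size - 1)
            pad = GenomicInterval(r.chrom, max(1, start - margin),
                                  iv.end + margin)
            if all(not pad.overlaps(c) for c in chosen):
                chosen.append(iv)
                break
        else:
            raise RuntimeError("could not place spike intervals")
    return chosen


@dataclass
class BenchmarkResult:
    """Aggregated spike-in benchmark outcome.

    ``per_size`` has one row per (kind, size, threshold) with detection
    counts, rates, and Clopper-Pearson binomial 95% confidence bounds.
    """

    per_size: pd.DataFrame
    additional_fps: pd.DataFrame
    thresholds: tuple[float, ...]
    n_instances: int

    def rate(self, kind: str, size: int, threshold: float = 0.25) -> float:
        df = self.per_size
        row = df[(df["kind"] == kind) & (df["size"] == size)
                 & (df["threshold"] == threshold)]
        if row.empty:
            raise KeyError((kind, size, threshold))
        return float(row["rate"].iloc[0])

    def sensitivity(self, size: int, threshold: float = 0.25) -> float:
        return self.rate("de_novo", size, threshold)

    def inherited_de_novo_rate(self, size: int | None = None,
                               threshold: float = 0.25) -> float:
        if size is not None:
            return self.rate("inherited", size, threshold)
        df = self.per_size
        sel = df[(df["kind"] == "inherited") & (df["threshold"] == threshold)]
        return float(sel["n_detected"].sum() / sel["n"].sum())

    def to_json_summary(self) -> dict:
        return {
            "n_instances": self.n_instances,
            "thresholds": list(self.thresholds),
            "per_size": self.per_size.to_dict(orient="records"),
            "n_additional_false_positives": int(len(self.additional_fps)),
            "fp_widths": self.additional_fps["size"].tolist()
            if len(self.additional_fps) else [],
        }


def mscore_deletion_calibration(seed: int = 137, n_replicates: int = 8,
                                n_bins: int = 400, n_samples: int = 40,
                                coverage: int = 160,
                                deleted_bins: int = 10
                                ) -> tuple[float, float]:
    """Calibration of the M score against a simulated one-copy deletion.

    Each replicate draws a Poisson bins-by-samples count matrix at the
    given per-bin mean, halves one sample's counts (binomial thinning,
    p = 0.5) over a contiguous run of ``deleted_bins`` bins, normalizes,
    and records that sample's mean M over the deleted run plus the grand
    mean of all copy-neutral cells.  Returns the two means averaged over
    replicates: a low-noise estimate of the expected M for a
    heterozygous deletion (theory: -1) and for copy-neutral DNA
    (theory: 0).
    """
    from .binning import Bin
    rng = np.random.default_rng(seed)
    del_means = []
    neutral_means = []
    for _ in range(n_replicates):
        counts = rng.poisson(coverage, size=(n_bins, n_samples))
        start = int(rng.integers(0, n_bins - deleted_bins))
        region = slice(start, start + deleted_bins)
        counts[region, 0] = rng.binomial(counts[region, 0], 0.5)
        gc = rng.uniform(0.3, 0.6, n_bins)
        bins = [Bin(GenomicInterval("chr1", 1 + 200 * k, 200 + 200 * k),
                    gc=float(gc[k]), mappability=1.0, qc_pass=True)
                for k in range(n_bins)]
        m = _norm.normalize_counts(counts, bins,
                                   [f"s{k}" for k in range(n_samples)]).m
        del_means.append(float(m[region, 0].mean()))
        neutral_means.append(float(np.delete(m, 0, axis=1).mean()))
    return float(np.mean(del_means)), float(np.mean(neutral_means))


def _binom_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval for a binomial proportion."""
    if n == 0:
        return float("nan"), float("nan")
    a = (1 - level) / 2
    lo = stats.beta.ppf(a, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - a, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def benchmark_cbs_config(seed: int = 137) -> CBSConfig:
    """Desk-scale CBS settings: study alpha/min-width/sd-undo, 1000 perms."""
    return CBSConfig(alpha=0.001, min_width=3, undo_sd=4.0,
                     n_permutations=1000, rng_seed=seed)


def run_benchmark(n_trios: int = 50, n_replicates: int = 5,
                  sizes: Sequence[int] = (250, 500, 1000, 2000, 4000),
                  seed: int = 137,
                  thresholds: Sequence[float] = (0.0, 0.25, 0.5),
                  drop_probability: float = 0.5,
                  binning_config: BinningConfig | None = None,
                  cbs_config: CBSConfig | None = None,
                  calling_config: CallingConfig | None = None,
                  genome: ToyGenome | None = None,
                  profile: CaptureProfile | None = None,
                  progress: bool = False) -> BenchmarkResult:
    """The spike-in benchmark: spike, run the pipeline, score.

    Each replicate simulates a fresh cohort of ``n_trios`` trios, builds
    bins and baseline M scores once, then treats every QC-passing trio
    as one spiked instance: 5 de novo and 5 inherited deletions of the
    given sizes are spiked into that trio's reads (drop probability
    0.5), the affected sample columns are re-normalized, and the full
    minimum-distance / CBS / calling chain runs for that trio.  Truth
    intervals are scored at every overlap threshold.
    """
    master = np.random.default_rng(seed)
    if genome is None:
        genome = build_toy_genome(int(master.integers(2 ** 31)))
    if profile is None:
        profile = make_capture_profile(genome, int(master.integers(2 ** 31)))
    binning_config = binning_config or BinningConfig(
        rng_seed=int(master.integers(2 ** 31)))
    cbs_config = cbs_config or benchmark_cbs_config(
        int(master.integers(2 ** 31)))
    calling_config = calling_config or CallingConfig()

    det_records: list[dict] = []
    fp_records: list[dict] = []
    n_instances = 0

    for rep in range(n_replicates):
        rep_rng = np.random.default_rng(int(master.integers(2 ** 31)))
        cohort = generate_cohort(profile, n_trios, rep_rng)
        bins = build_bins_from_cohort(cohort, binning_config)
        good_bins = qc_passing(bins)
        samples = cohort.samples
        counts = np.column_stack(
            [count_readset(cohort.readsets[s], good_bins) for s in samples])
        gc_arr = np.array([b.gc for b in good_bins])
        # baseline normalization and cohort-level artifacts
        logc = _norm.log_transform(counts)
        col_centered = logc - np.median(logc, axis=0, keepdims=True)
        row_med = np.median(col_centered, axis=1, keepdims=True)
        centered = col_centered - row_med
        m_all = _norm.covariate_adjust(centered, good_bins)
        baseline = MScoreMatrix(list(good_bins), list(samples), m_all)
        flags = flag_variable_bins(baseline, calling_config)
        col_of = {s: k for k, s in enumerate(samples)}

        eligible = []
        for t in cohort.trios:
            qc = family_qc(compute_md_track(baseline, t))
            if qc.passed:
                eligible.append(t)
            elif progress:
                print(f"rep {rep}: {t.family_id} fails family QC: {qc.reason}")

        for trio in eligible:
            inst_rng = np.random.default_rng(int(rep_rng.integers(2 ** 31)))
            try:
                spots = _sample_spike_intervals(
                    profile.regions, list(sizes) * 2, inst_rng)
            except RuntimeError:
                warnings.warn("spike placement failed; skipping instance")
                continue
            truth: list[SpikeTruth] = []
            for k, size in enumerate(sizes):
                truth.append(SpikeTruth(trio.family_id, spots[k], "de_novo",
                                        "none", drop_probability))
            for k, size in enumerate(sizes):
                parent = "father" if inst_rng.random() < 0.5 else "mother"
                truth.append(SpikeTruth(trio.family_id, spots[len(sizes) + k],
                                        "inherited", parent, drop_probability))
            # spike reads
            spiked: dict[str, ReadSet] = {
                trio.offspring_id: cohort.readsets[trio.offspring_id]}
            for t in truth:
                spiked[trio.offspring_id] = spike_deletion(
                    spiked[trio.offspring_id], t.interval,
                    t.drop_probability, inst_rng)
                if t.kind == "inherited":
                    pid = (trio.father_id if t.carrier_parent == "father"
                           else trio.mother_id)
                    spiked.setdefault(pid, cohort.readsets[pid])
                    spiked[pid] = spike_deletion(
                        spiked[pid], t.interval, t.drop_probability, inst_rng)
            # exact re-normalization of the affected columns
            logc_inst = col_centered.copy()
            changed = []
            for sid, rs in spiked.items():
                col = count_readset(rs, good_bins).astype(float)
                lc = np.log2(col + 1.0)
                logc_inst[:, col_of[sid]] = lc - np.median(lc)
                changed.append(col_of[sid])
            row_med_inst = np.median(logc_inst, axis=1, keepdims=True)
            trio_cols = [col_of[s] for s in trio.members]
            m_trio = np.empty((len(good_bins), 3))
            for j, c in enumerate(trio_cols):
                y = logc_inst[:, c] - row_med_inst[:, 0]
                m_trio[:, j] = _norm._loess_residual(y, gc_arr, 0.75)
            mm = MScoreMatrix(list(good_bins), list(trio.members), m_trio)
            track = compute_md_track(mm, trio)
            segments = segment_md_track(track, profile.regions, cbs_config)
            calls = call_de_novo(segments, flags, calling_config)
            n_instances += 1
            for thr in thresholds:
                frag = score_calls(calls, truth, thr)
                for t, hit in frag.detected.items():
                    det_records.append({
                        "replicate": rep, "family_id": t.family_id,
                        "kind": t.kind, "size": t.interval.size,
                        "threshold": thr, "detected": bool(hit)})
                if thr == (0.25 if 0.25 in thresholds else thresholds[0]):
                    for c, inh in zip(frag.false_positives,
                                      frag.fp_matched_inherited):
                        fp_records.append({
                            "replicate": rep, "family_id": c.family_id,
                            "chrom": c.interval.chrom,
                            "start": c.interval.start,
                            "end": c.interval.end, "size": c.size,
                            "matched_inherited": inh})
        if progress:
            print(f"replicate {rep + 1}/{n_replicates} done "
                  f"({n_instances} instances)")

    det = pd.DataFrame(det_records)
    rows = []
    if len(det):
        for (kind, size, thr), grp in det.groupby(["kind", "size",
                                                   "threshold"]):
            k, n = int(grp["detected"].sum()), len(grp)
            lo, hi = _binom_ci(k, n)
            rows.append({"kind": kind, "size": size, "threshold": thr,
                         "n": n, "n_detected": k, "rate": k / n,
                         "ci_low": lo, "ci_high": hi})
    per_size = pd.DataFrame(
        rows, columns=["kind", "size", "threshold", "n", "n_detected",
                       "rate", "ci_low", "ci_high"])
    fps = pd.DataFrame(fp_records, columns=["replicate", "family_id", "chrom",
                                            "start", "end", "size",
                                            "matched_inherited"])
    return BenchmarkResult(per_size, fps, tuple(thresholds), n_instances)
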