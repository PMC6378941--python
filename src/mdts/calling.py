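"""Candidate de novo deletion calls from segmented minimum distances.

A segment becomes a candidate when its mean minimum distance lies within
0.3 of the theoretical single-copy-deletion value of -1, i.e. in the
closed interval [-1.3, -0.7].  To guard against normalization failures
at copy-number polymorphisms, bins where more than 5% of samples have M
scores outside [-0.5, 0.5] are flagged as highly variable, and a
candidate is reported only when more than half of its bins are
unflagged; other candidates are kept with status ``suppressed`` for
auditability.

A lightweight read-pair evidence inspector annotates calls with the
number of aberrantly spaced (discordant) pairs spanning them in each
trio member's BAM — the "Z-shaped" pattern of long-insert pairs
flanking a deletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .genomic_io import GenomicInterval, SampleAlignments
from .normalization import MScoreMatrix
from .segmentation import Segment

MIN_SAMPLES_FOR_FLAGS = 20


@dataclass(frozen=True)
class CallingConfig:
    target_md: float = -1.0
    md_tolerance: float = 0.3
    variability_sample_fraction: float = 0.05
    variability_m_bounds: tuple[float, float] = (-0.5, 0.5)
    min_unflagged_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.md_tolerance <= 0:
            raise ValueError("md_tolerance must be positive")
        if not (0 < self.variability_sample_fraction < 1):
            raise ValueError("variability_sample_fraction must be in (0, 1)")


@dataclass
class DeNovoCall:
    family_id: str
    interval: GenomicInterval
    n_bins: int
    mean_md: float
    n_flagged_bins: int
    status: str  # "reported" | "suppressed"
    discordant_pair_counts: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.interval.size


def flag_variable_bins(mscores: MScoreMatrix,
                       config: CallingConfig | None = None) -> np.ndarray:
    """Boolean flag per bin: True where the cohort is highly variable.

    A bin is flagged iff strictly more than
    ``variability_sample_fraction`` of samples have M scores outside the
    closed interval ``variability_m_bounds``.
    """
    config = config or CallingConfig()
    n_samples = len(mscores.samples)
    if n_samples < MIN_SAMPLES_FOR_FLAGS:
        warnings.warn(f"only {n_samples} samples; the "
                      f"{config.variability_sample_fraction:.0%} variability "
                      "rule is unreliable below 20 samples")
    lo, hi = config.variability_m_bounds
    outside = (mscores.m < lo) | (mscores.m > hi)
    frac = outside.sum(axis=1) / n_samples
    return frac > config.variability_sample_fraction


def call_de_novo(segments: Sequence[Segment], flags: np.ndarray,
                 config: CallingConfig | None = None) -> list[DeNovoCall]:
    """Candidate calls from segments; flags must share the segments' bin frame.

    Candidates (mean_d within tolerance of the target) are returned with
    status ``reported`` when more than ``min_unflagged_fraction`` of
    their bins are unflagged, else ``suppressed``.
    """
    config = config or CallingConfig()
    flags = np.asarray(flags, dtype=bool)
    lo = config.target_md - config.md_tolerance
    hi = config.target_md + config.md_tolerance
    calls: list[DeNovoCall] = []
    for seg in segments:
        if not (lo <= seg.mean_d <= hi):
            continue
        seg_flags = flags[seg.bin_start_index:seg.bin_end_index + 1]
        n_flagged = int(seg_flags.sum())
        unflagged_frac = (seg.n_bins - n_flagged) / seg.n_bins
        status = ("reported"
                  if unflagged_frac > config.min_unflagged_fraction
                  else "suppressed")
        calls.append(DeNovoCall(
            family_id=seg.trio.family_id if seg.trio else "",
            interval=seg.interval, n_bins=seg.n_bins,
            mean_md=float(seg.mean_d), n_flagged_bins=n_flagged,
            status=status))
    return calls


def reported(calls: Sequence[DeNovoCall]) -> list[DeNovoCall]:
    return [c for c in calls if c.status == "reported"]


# ---------------------------------------------------------------------------
# read-pair evidence
# ---------------------------------------------------------------------------

@dataclass
class ReadPairEvidence:
    sample_id: str
    available: bool
    n_proper_pairs: int = 0
    n_discordant_pairs: int = 0
    fragment_mean: float = float("nan")
    fragment_sd: float = float("nan")
    pair_table: pd.DataFrame | None = None


def _fragment_stats(af: pysam.AlignmentFile,
                    max_pairs: int = 10_000) -> tuple[float, float]:
    """Mean and SD of the inferred fragment length from proper pairs."""
    tlens = []
    for read in af.fetch():
        if read.is_proper_pair and read.template_length > 0 \
                and not read.is_secondary and not read.is_supplementary:
            tlens.append(read.template_length)
            if len(tlens) >= max_pairs:
                break
    if len(tlens) < 2:
        return float("nan"), float("nan")
    arr = np.asarray(tlens, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))


def read_pair_evidence(alignments: Mapping[str, SampleAlignments | str],
                       call: DeNovoCall, flank: int = 1000,
                       k_sd: float = 5.0) -> dict[str, ReadPairEvidence]:
    """Count discordant read pairs spanning a call, per trio member.

    A pair is discordant when its inferred fragment length exceeds the
    sample's fragment mean plus ``k_sd`` standard deviations (estimated
    from up to 10 000 proper pairs) and it spans the call interval.  A
    missing BAM marks evidence unavailable without affecting the call.
    The per-member table lists pair spans sorted by mate-1 start, ready
    for plotting.
    """
    iv = call.interval
    out: dict[str, ReadPairEvidence] = {}
    for sid, aln in alignments.items():
        if isinstance(aln, str):
            aln = SampleAlignments(sid, aln)
        try:
            af = aln.open()
        except (FileNotFoundError, OSError, ValueError):
            out[sid] = ReadPairEvidence(sid, available=False)
            continue
        with af:
            fmean, fsd = _fragment_stats(af)
            cutoff = (fmean + k_sd * fsd) if np.isfinite(fmean) else np.inf
            rows = []
            n_proper = n_disc = 0
            if iv.chrom in af.references:
                lo = max(0, iv.start - 1 - flank)
                for read in af.fetch(iv.chrom, lo, iv.end + flank):
                    if (read.is_secondary or read.is_supplementary
                            or read.is_unmapped or read.template_length <= 0):
                        continue
                    start1 = read.reference_start + 1
                    frag_end = start1 + read.template_length - 1
                    spans = start1 <= iv.start and frag_end >= iv.end
                    if read.is_proper_pair:
                        n_proper += int(spans)
                    if read.template_length > cutoff and spans:
                        n_disc += 1
                        rows.append((start1, frag_end, read.template_length))
                    elif read.is_proper_pair:
                        rows.append((start1, frag_end, read.template_length))
            table = pd.DataFrame(rows, columns=["mate1_start", "fragment_end",
                                                "fragment_length"])
            table = table.sort_values("mate1_start", kind="stable",
                                      ignore_index=True)
            out[sid] = ReadPairEvidence(
                sid, available=True, n_proper_pairs=n_proper,
                n_discordant_pairs=n_disc, fragment_mean=fmean,
                fragment_sd=fsd, pair_table=table)
    return out


def annotate_evidence(call: DeNovoCall,
                      evidence: Mapping[str, ReadPairEvidence]) -> None:
    call.discordant_pair_counts = {
        sid: (ev.n_discordant_pairs if ev.available else None)
        for sid, ev in evidence.items()}


def calls_to_frame(calls: Sequence[DeNovoCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "family_id": c.family_id, "chrom": c.interval.chrom,
            "start": c.interval.start, "end": c.interval.end,
            "size": c.size, "n_bins": c.n_bins,
            "MD": round(c.mean_md, 6), "n_flagged_bins": c.n_flagged_bins,
            "status": c.status,
            "discordant_pairs": ";".join(
                f"{k}={v}" for k, v in c.discordant_pair_counts.items()),
        })
    cols = ["family_id", "chrom", "start", "end", "size", "n_bins", "MD",
            "n_flagged_bins", "status", "discordant_pairs"]
    return pd.DataFrame(rows, columns=cols)


def write_calls(calls: Sequence[DeNovoCall], tsv_path, bed_path=None) -> None:
    df = calls_to_frame(calls)
    df.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        from .genomic_io import write_bed
        rep = reported(calls)
        write_bed([c.interval for c in rep], bed_path,
                  names=[c.family_id for c in rep])
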