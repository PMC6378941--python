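"""End-to-end pipeline: bins -> counts -> M scores -> minimum distance ->
CBS -> de novo deletion calls.

All stage outputs are plain TSV/BED/JSON written with fixed numeric
formatting, and every random choice is seeded, so a rerun with the same
config regenerates byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import Bin, BinningConfig, build_bins, qc_passing, subsample_samples
from .calling import (CallingConfig, annotate_evidence, call_de_novo,
                      flag_variable_bins, read_pair_evidence, reported,
                      write_calls)
from .genomic_io import (CountMatrix, MappabilityTrack, ReadFilterConfig,
                         SampleAlignments, count_reads_in_bins,
                         fetch_read_spans, read_bed, write_bed)
from .normalization import normalize_counts
from .segmentation import CBSConfig, segment_md_track
from .trio_stats import (Trio, compute_md_track, family_qc, read_pedigree,
                         trios_from_pedigree)


@dataclass
class PipelineConfig:
    bam_paths: dict[str, str]          # sample_id -> BAM path
    pedigree: str
    reference: str
    targets: str                       # BED of targeted regions
    outdir: str
    mappability: str | None = None     # bedGraph; None -> constant 1.0
    sample_metadata: str | None = None  # TSV: sample_id, batch, qc_pass
    binning: BinningConfig = field(default_factory=BinningConfig)
    cbs: CBSConfig = field(default_factory=CBSConfig)
    calling: CallingConfig = field(default_factory=CallingConfig)
    filters: ReadFilterConfig = field(default_factory=ReadFilterConfig)
    loess_span: float = 0.75
    annotate_read_pairs: bool = True
    rng_seed: int = 137


@dataclass
class RunManifest:
    families_in: int = 0
    families_excluded_batch: int = 0
    families_excluded_mdqc: int = 0
    families_analyzed: int = 0
    bins_built: int = 0
    bins_qc_passed: int = 0
    n_segments: int = 0
    n_candidates: int = 0
    n_reported: int = 0
    config_hash: str = ""
    outputs: dict = field(default_factory=dict)

    def check_conservation(self) -> bool:
        return (self.families_in == self.families_excluded_batch
                + self.families_excluded_mdqc + self.families_analyzed)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def batch_qc_filter(trios: Sequence[Trio],
                    batch_labels: Mapping[str, str] | None = None,
                    qc_fail: set | None = None) -> tuple[list[Trio], int]:
    """Drop families spanning batches or containing a lab-QC failure.

    With no batch labels the filter is skipped (warning).  Returns the
    retained trios and the number excluded.
    """
    if batch_labels is None and qc_fail is None:
        warnings.warn("no batch/QC metadata provided; batch filter skipped")
        return list(trios), 0
    kept = []
    for t in trios:
        if qc_fail and any(s in qc_fail for s in t.members):
            continue
        if batch_labels is not None:
            batches = {batch_labels.get(s) for s in t.members}
            if len(batches) > 1:
                continue
        kept.append(t)
    return kept, len(trios) - len(kept)


def _load_metadata(path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    batches = None
    qc_fail = None
    if "batch" in df.columns:
        batches = dict(zip(df["sample_id"], df["batch"]))
    if "qc_pass" in df.columns:
        qc_fail = set(df.loc[df["qc_pass"].str.lower()
                             .isin(["0", "false", "fail", "no"]),
                             "sample_id"])
    return batches, qc_fail


def _bins_sidecar(bins: Sequence[Bin], path) -> None:
    df = pd.DataFrame({
        "chrom": [b.interval.chrom for b in bins],
        "start": [b.interval.start for b in bins],
        "end": [b.interval.end for b in bins],
        "gc": [round(b.gc, 6) for b in bins],
        "mappability": [round(b.mappability, 6) for b in bins],
        "qc_pass": [int(b.qc_pass) for b in bins],
    })
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and write outputs under ``config.outdir``."""
    import pyfaidx

    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)
    manifest = RunManifest()
    # hash only the analytic parameters, not file locations, so reruns
    # of the same analysis in different directories compare equal
    analytic = repr((config.binning, config.cbs, config.calling,
                     config.filters, config.loess_span, config.rng_seed))
    manifest.config_hash = hashlib.sha256(analytic.encode()).hexdigest()[:16]

    # --- families ---------------------------------------------------------
    ped = read_pedigree(config.pedigree)
    trios = trios_from_pedigree(ped)
    manifest.families_in = len(trios)
    if config.sample_metadata:
        batches, qc_fail = _load_metadata(config.sample_metadata)
        trios, n_excl = batch_qc_filter(trios, batches, qc_fail)
    else:
        n_excl = 0
    manifest.families_excluded_batch = n_excl
    if not trios:
        manifest.families_analyzed = 0
        manifest.write(out("manifest.json"))
        return manifest

    samples = [s for t in trios for s in t.members]
    alns = {s: SampleAlignments(s, config.bam_paths[s]) for s in samples}
    targets = read_bed(config.targets)
    fasta = pyfaidx.Fasta(config.reference)
    mtrack = (MappabilityTrack.from_bedgraph(config.mappability)
              if config.mappability else MappabilityTrack.constant(1.0))

    # --- bins -------------------------------------------------------------
    sub = subsample_samples(samples, config.binning)
    coverage_by_region = {}
    spans_by_region = {}
    for k, region in enumerate(targets):
        covs = []
        spans = {}
        for sid in sub:
            st, en = fetch_read_spans(alns[sid], region, config.filters)
            from .genomic_io import coverage_from_spans, CoverageVector
            covs.append(CoverageVector(region.chrom, region.start,
                                       coverage_from_spans(st, en, region)))
            spans[sid] = (st, en)
        coverage_by_region[k] = covs
        spans_by_region[k] = spans
    bins = build_bins(targets, coverage_by_region, spans_by_region,
                      fasta, mtrack, config.binning)
    manifest.bins_built = len(bins)
    good = qc_passing(bins)
    manifest.bins_qc_passed = len(good)
    write_bed([b.interval for b in bins], out("bins.bed"))
    _bins_sidecar(bins, out("bins.tsv"))

    # --- counts -----------------------------------------------------------
    counts = np.column_stack(
        [count_reads_in_bins(alns[s], good, config.filters) for s in samples])
    cm = CountMatrix(list(good), list(samples), counts)
    cm.to_tsv(out("counts.tsv"))

    # --- M scores ---------------------------------------------------------
    mscores = normalize_counts(counts, good, samples,
                               loess_span=config.loess_span)
    mscores.to_tsv(out("mscores.tsv"))
    flags = flag_variable_bins(mscores, config.calling)

    # --- minimum distance + family QC ------------------------------------
    qc_rows = []
    passing = []
    tracks = {}
    for t in trios:
        track = compute_md_track(mscores, t)
        stats_ = family_qc(track)
        qc_rows.append({
            "family_id": t.family_id,
            "lag10_autocorrelation": round(stats_.lag10_autocorrelation, 6),
            "variance": round(stats_.variance, 6),
            "pass": int(stats_.passed), "reason": stats_.reason})
        if stats_.passed:
            passing.append(t)
            tracks[t.family_id] = track
    pd.DataFrame(qc_rows).to_csv(out("family_qc.tsv"), sep="\t", index=False)
    manifest.families_excluded_mdqc = len(trios) - len(passing)
    manifest.families_analyzed = len(passing)

    md_df = pd.DataFrame({
        "chrom": [b.interval.chrom for b in good],
        "start": [b.interval.start for b in good],
        "end": [b.interval.end for b in good]})
    for t in passing:
        col = np.full(len(good), np.nan)
        tr = tracks[t.family_id]
        col[tr.bin_indices] = tr.d
        md_df[t.family_id] = col
    md_df.to_csv(out("minimum_distance.tsv"), sep="\t", index=False,
                 float_format="%.6g")

    # --- segmentation + calling ------------------------------------------
    seg_rows = []
    all_calls = []
    for t in passing:
        track = tracks[t.family_id]
        segments = segment_md_track(track, targets, config.cbs)
        for s in segments:
            seg_rows.append({
                "family_id": t.family_id, "chrom": s.interval.chrom,
                "start": s.interval.start, "end": s.interval.end,
                "n_bins": s.n_bins, "mean_d": round(s.mean_d, 6)})
        track_flags = flags[track.bin_indices]
        calls = call_de_novo(segments, track_flags, config.calling)
        if config.annotate_read_pairs:
            member_alns = {s: alns[s] for s in t.members}
            for c in reported(calls):
                annotate_evidence(c, read_pair_evidence(member_alns, c))
        all_calls.extend(calls)
    pd.DataFrame(seg_rows, columns=["family_id", "chrom", "start", "end",
                                    "n_bins", "mean_d"]).to_csv(
        out("segments.tsv"), sep="\t", index=False)
    manifest.n_segments = len(seg_rows)
    manifest.n_candidates = len(all_calls)
    manifest.n_reported = len(reported(all_calls))
    write_calls(all_calls, out("calls.tsv"), out("calls.bed"))

    manifest.outputs = {name: os.path.basename(out(name)) for name in
                        ["bins.bed", "bins.tsv", "counts.tsv", "mscores.tsv",
                         "family_qc.tsv", "minimum_distance.tsv",
                         "segments.tsv", "calls.tsv", "calls.bed"]}
    manifest.write(out("manifest.json"))
    return manifest
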