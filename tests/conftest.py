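"""Shared fixtures: small synthetic BAM cohorts and the session benchmark."""

from __future__ import annotations

import os

import numpy as np
import pysam
import pytest

from mdts.binning import BinningConfig
from mdts.genomic_io import GenomicInterval, write_bed
from mdts.segmentation import CBSConfig
from mdts.simulation import (build_toy_genome, generate_cohort,
                             make_capture_profile, run_benchmark,
                             spike_deletion, write_readset_bam)


def write_simple_bam(path, chrom_lengths: dict[str, int],
                     reads: list[tuple]) -> str:
    """Write a coordinate-sorted, indexed BAM from explicit read tuples.

    Each read is ``(chrom, start_1based, length)`` or
    ``(chrom, start_1based, length, mapq, flag)``.
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()]}
    tid = {c: k for k, c in enumerate(chrom_lengths)}
    rows = []
    for k, r in enumerate(reads):
        chrom, start, length = r[0], r[1], r[2]
        mapq = r[3] if len(r) > 3 else 60
        flag = r[4] if len(r) > 4 else 0
        rows.append((tid[chrom], start - 1, length, mapq, flag, f"r{k}"))
    rows.sort(key=lambda t: (t[0], t[1], t[5]))
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for rtid, pos, length, mapq, flag, name in rows:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = rtid
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigartuples = [(0, length)]
            bam.write(a)
    pysam.index(str(path))
    return str(path)


@pytest.fixture(scope="session")
def small_genome():
    """Compact toy genome: 6 capture regions on short chromosomes.

    Large enough (~70 kb of capture, ~550 bins) that a single spiked
    deletion stays a realistic fraction of the bin set and does not
    inflate family-level variance QC.
    """
    return build_toy_genome(seed=20, n_regions=6, n_chroms=2,
                            chrom_length=600_000,
                            region_size_range=(9_000, 16_000))


@pytest.fixture(scope="session")
def small_profile(small_genome):
    return make_capture_profile(small_genome, seed=21)


@pytest.fixture(scope="session")
def pipeline_cohort(tmp_path_factory, small_genome, small_profile):
    """A 7-trio BAM cohort with one 2 kb de novo deletion spiked into the
    first proband, plus all pipeline input files.

    7 trios give 21 samples, so a single deletion carrier stays at or
    below the 5% cohort-variability flag threshold, as in a real study.
    """
    root = tmp_path_factory.mktemp("cohort")
    rng = np.random.default_rng(42)
    cohort = generate_cohort(small_profile, 7, rng)
    region = small_genome.regions[1]
    mid = (region.start + region.end) // 2
    spike = GenomicInterval(region.chrom, mid - 600, mid + 599)
    proband = cohort.trios[0].offspring_id
    cohort.readsets[proband] = spike_deletion(
        cohort.readsets[proband], spike, 0.5, np.random.default_rng(43))

    fasta = os.path.join(root, "reference.fa")
    small_genome.write_fasta(fasta)
    targets = os.path.join(root, "targets.bed")
    write_bed(small_genome.regions, targets)
    pedigree = os.path.join(root, "pedigree.tsv")
    with open(pedigree, "w") as fh:
        fh.write("family_id\toffspring\tfather\tmother\n")
        for t in cohort.trios:
            fh.write(f"{t.family_id}\t{t.offspring_id}\t{t.father_id}"
                     f"\t{t.mother_id}\n")
    bam_paths = {}
    for sid, rs in cohort.readsets.items():
        p = os.path.join(root, f"{sid}.bam")
        write_readset_bam(rs, small_genome, p)
        bam_paths[sid] = p
    return {"root": root, "cohort": cohort, "spike": spike,
            "spiked_family": cohort.trios[0].family_id, "fasta": fasta,
            "targets": targets, "pedigree": pedigree, "bam_paths": bam_paths}


def _make_pipeline_config(cohort_files, outdir):
    from mdts.pipeline import PipelineConfig

    return PipelineConfig(
        bam_paths=cohort_files["bam_paths"],
        pedigree=cohort_files["pedigree"],
        reference=cohort_files["fasta"],
        targets=cohort_files["targets"],
        outdir=str(outdir),
        binning=BinningConfig(rng_seed=137),
        cbs=CBSConfig(n_permutations=2000, rng_seed=137),
        rng_seed=137,
    )


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory, pipeline_cohort):
    """The full pipeline executed twice with seed 137 on the same inputs."""
    from mdts.pipeline import run_pipeline

    outs = []
    manifests = []
    for tag in ("run1", "run2"):
        outdir = tmp_path_factory.mktemp(tag)
        cfg = _make_pipeline_config(pipeline_cohort, outdir)
        manifests.append(run_pipeline(cfg))
        outs.append(outdir)
    return {"outdirs": outs, "manifests": manifests,
            "cohort_files": pipeline_cohort}


@pytest.fixture(scope="session")
def benchmark_result():
    """The scaled spike-in benchmark: 50 trios x 5 replicates, seed 137."""
    return run_benchmark(n_trios=50, n_replicates=5, seed=137)
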