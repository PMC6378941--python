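# Methods

`mdts` detects de novo heterozygous copy-number deletions in
parent-offspring trios sequenced on capture-based targeted platforms.
This note documents the model, the defaults and why they are what they
are, the synthetic data the package tests itself against, and the
numerical choices made where the design was genuinely open.

## The statistical model

Read depth in capture sequencing is informative about copy number only
where capture succeeded, and capture efficiency varies by orders of
magnitude along a targeted region. The method therefore avoids
fixed-width windows entirely and lets the data define the analysis unit.

**Coverage-adaptive bins.** A random subsample of `n_subsample = 25`
samples defines *proto-regions*: maximal runs of bases where at least
one subsampled sample has depth ≥ `proto_min_depth = 10`. Each
proto-region is partitioned left to right into the smallest windows
whose median read count (lower median, across the subsample) reaches
`min_median_reads = 160`; the trailing remainder merges into the last
closed bin, and a proto-region that never reaches the target stays one
bin. Because per-sample overlap counts are non-decreasing in the window
end, the closing base is found by bisection, which is exactly equivalent
to the per-base scan. The 160-read target is not arbitrary: under a
Poisson model a copy-neutral bin with mean c reads sits
(c − c/2)/√c = √c/2 standard deviations away from a heterozygous
deletion, and c = 160 gives 6.3 SD — single-bin deletions are already
well separated. Bins with mean mappability < 0.75 or GC outside the
closed range [0.15, 0.85] are excluded before counting. With no
mappability track supplied, a constant 1.0 track is used so the pipeline
runs without external downloads.

**M scores.** Counts (reads overlapping a bin by ≥ 1 bp; mates counted
independently) are transformed as log2(count + 1), centered by the
sample-column medians then the bin-row medians (a single pass each, not
an iterated polish), and each sample is loess-adjusted against bin GC
and then bin mappability, subtracting each fit. The result is a relative
copy-number score: ≈ 0 for copy-neutral DNA, ≈ −1 for a single-copy
deletion. Centering against the cohort is what turns raw depth into
copy number; it assumes deletions are rare in the cohort at any given
bin, which is why copy-number polymorphisms need the variability flag
below.

**Minimum distance.** Per bin, with offspring/father/mother scores
M_O, M_F, M_M:

    δ_F = M_O − M_F,  δ_M = M_O − M_M,  d = argmin_{δ∈{δ_F,δ_M}} |δ|

(ties resolve to δ_F — deterministic and role-symmetric in magnitude).
A deletion inherited from one parent cancels in the difference to that
parent, so d ≈ 0; only events absent from both parents drive d to −1.
Shared technical variation between family members cancels in the same
way, which is the second advantage of differencing within trios.

**Family QC.** Trios whose minimum-distance track has lag-10
autocorrelation > 0.4 or variance > 0.05 are excluded; both statistics
are computed on the concatenated, genomically ordered track (the biased
autocorrelation estimator; variance with ddof = 1; a constant track has
autocorrelation 0 by convention). Tracks shorter than 11 bins fail with
an explicit reason.

**Segmentation.** Circular binary segmentation per targeted region per
trio: the circularized two-sample t statistic is maximized over all arcs
with both arc and complement at least `min_width = 3` bins, and the
split is accepted when its permutation p-value (empirical exceedance
fraction over within-segment shuffles) is ≤ `alpha = 0.001`. Accepted
splits recurse. Afterwards, adjacent segments are greedily merged
(smallest gap first) while their mean difference is below
`undo_sd = 4` noise SDs, the noise SD being 1.4826·MAD(lag-1
differences)/√2 — robust to the change points being tested. All
randomness flows from one seeded generator (default seed 137), so
segmentations are reproducible bit for bit.

**Calling.** A segment is a candidate when its mean minimum distance
lies in the closed band [−1.3, −0.7] (within 0.3 of the theoretical
−1). Bins where strictly more than 5% of samples have M scores outside
[−0.5, 0.5] are flagged as highly variable (copy-number polymorphisms
and normalization failures); a candidate is *reported* only when
strictly more than half of its bins are unflagged, and is otherwise kept
with status `suppressed` for audit. Reported calls can be annotated with
read-pair evidence: pairs whose inferred fragment length exceeds the
sample's fragment mean + 5 SD (estimated from up to 10 000 proper pairs)
and which span the call — the "Z-shaped" discordant-pair signature of a
real deletion.

## Numerical and design choices

* **Permutation p-value.** Plain empirical exceedance count/nperm, no
  hybrid tail approximation. The permutation loop stops as soon as the
  exceedance count exceeds ⌊alpha·nperm⌋ (significance has become
  impossible); this changes speed only, never the decision. Library
  default `n_permutations = 10000`; the benchmark driver uses 1000
  (= 1/alpha, the smallest count that can resolve alpha) to keep the
  250-instance experiment on one core in minutes.
* **Max-statistic search.** Exact over all O(n²) arcs, vectorized per
  arc length via sliding-window cumulative sums; verified against an
  exhaustive scan in the tests. Ties go to the leftmost (i, then j)
  boundary. When the optimal arc would strand a flank shorter than
  `min_width`, the boundary snaps to the segment edge; if both snap, no
  split is made.
* **Loess.** statsmodels lowess, span 0.75, sequential GC-then-
  mappability fits, `delta` interpolation at 1% of the covariate range
  for speed. A near-constant covariate (e.g. the constant mappability
  default) is skipped. Fewer than 10 bins skips adjustment entirely
  (fit unstable; a warning is emitted). Loess is not a projection, so a
  second adjustment pass moves scores slightly (~0.006 sup-norm on
  trend-free data with noise SD 0.1); the property test bounds this at
  a tenth of the noise SD rather than at machine precision.
* **Median conventions.** Lower median across samples during binning
  (relevant for even subsample sizes); numpy's interpolated median for
  the centering steps.
* **Degenerate inputs.** Zero-variance segments produce no split;
  all-N bins have undefined GC and fail QC; bins with non-finite M in
  any trio member are masked out of that trio's track (index mapping is
  kept so cohort-level flags stay aligned); an unknown chromosome in a
  coverage query returns a zero vector with a warning, while a missing
  BAM index or reference chromosome is a hard error.

## The synthetic-data generator

The generator emulates the study conditions end to end: a deterministic
toy genome (4 chromosomes of 2 Mb) carries 13 disjoint capture regions
of 8–35 kb (≈ 230 kb of capture footprint in total) whose base
composition drifts smoothly over a GC range of roughly 0.22–0.68.
Paired-end 100 bp reads are placed by a Poisson process with a smooth,
heterogeneous per-region capture-intensity field (log-normal, ~0.3–3×),
Gaussian fragment lengths (mean 350, SD 60 bp), a mild smooth GC
acceptance bias centered at 45% GC, and a log-normal per-sample depth
scale (σ = 0.2, matching the study's spread of mean bin coverage —
MAD/median ≈ 14/66). The pair rate is calibrated so the median mean
per-bin coverage is ≈ 66×, which with the 160-read target yields bins a
couple of hundred base pairs wide. Reads exist both as in-memory span
arrays (the benchmark path — the identical counting/coverage kernels
the BAM readers call) and as coordinate-sorted, indexed BAMs emitted by
`simulate_trio_reads`, which the end-to-end pipeline and evidence tests
consume.

Deletions are spiked by dropping each read overlapping a chosen interval
independently with probability 0.5 — proband only (de novo) or proband
plus one randomly chosen parent (inherited). Mates are treated as
independent reads: a mate not overlapping the interval always survives.

**What the generator does not emulate:** sequencing errors and base
qualities, split reads, probe-level capture chemistry, batch effects,
reference biases, or genuine population CNP structure (CNP-like bins are
constructed directly in the unit tests instead). Passing the benchmark
therefore demonstrates the statistical machinery under realistic depth,
capture heterogeneity and sampling noise — not robustness to alignment
artifacts in real BAMs.

## The spike-in benchmark

Each of 5 replicates simulates a fresh cohort of 50 trios, builds bins
from a 25-sample subsample, counts all 150 samples, and computes
baseline M scores, cohort variability flags and family QC once. Every
QC-passing trio then becomes one spiked instance, mirroring the original
experiment where each iteration spiked one resampled trio against the
real cohort: 5 de novo and 5 inherited deletions of sizes
250/500/1000/2000/4000 bp are placed disjointly (300 bp apart, so two
spikes never share a bin) in the capture regions and spiked into that
trio's reads. Only the ≤ 3 affected sample columns are re-normalized —
exactly, since a sample's M scores depend on other samples only through
the bin-row medians, which are recomputed on the spiked matrix — and the
minimum-distance/CBS/calling chain runs for that trio. Variability flags
are the unspiked cohort's, as in the study where flags derive from the
real data. A truth deletion counts as called when the union of reported
calls covers ≥ 25% of its length (any-overlap and 50% thresholds are
also scored); reported calls matching no de novo truth are counted as
additional false positives, with calls matching inherited truths
tracked separately. Rates carry Clopper-Pearson 95% binomial intervals.

The problem sizes (50 trios × 5 replicates = 250 instances, ≈ 230 kb
footprint) are the package's desk-scale default; sizes, drop
probability, coverage and all filter thresholds are the study values.
At these settings the benchmark reproduces the expected behavior:
sensitivity ≈ 40/77/93/100/100% for 250/500/1000/2000/4000 bp de novo
deletions at the 25% threshold, no inherited deletion called de novo at
that threshold, and a handful of additional false positives across all
250 instances.

## Known limitations

* Autosomes only; duplications are out of scope (a positive-band
  analogue of the calling rule would be needed).
* The CBS p-value is purely empirical; with `n_permutations = 1/alpha`
  the significance resolution is exactly alpha.
* The read-pair evidence inspector is a heuristic annotator, not a
  breakpoint refiner; split-read realignment is out of scope.
* Multi-sibling families and quartets are not modeled; one trio per
  family.
* With fewer than ~20 samples the 5% variability rule degenerates (one
  carrier can flag a bin); the code warns in that regime.
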