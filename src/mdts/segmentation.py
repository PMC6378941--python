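"""Circular binary segmentation of minimum-distance tracks.

Change points in the per-bin minimum distances are found by recursive
circular binary segmentation: for the current stretch of bins, the
circularized two-sample t statistic is maximized over all arcs, and the
split is accepted when its permutation p-value (shuffling the stretch's
values) is at most ``alpha``.  Accepted splits recurse; afterwards,
adjacent segments whose mean difference is small relative to a robust
noise SD are merged back ("sd-undo").  Segmentation is performed per
targeted region and never across region gaps.

The permutation p-value is the plain empirical exceedance fraction; the
permutation loop stops early as soon as significance has become
impossible, which changes nothing but speed.  All randomness comes from
one seeded generator, so results are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genomic_io import GenomicInterval, _as_interval
from .trio_stats import MinimumDistanceTrack, Trio


@dataclass(frozen=True)
class CBSConfig:
    alpha: float = 0.001
    min_width: int = 3
    undo_sd: float = 4.0
    n_permutations: int = 10_000
    rng_seed: int = 137

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")
        if self.undo_sd < 0:
            raise ValueError("undo_sd must be >= 0")
        if self.n_permutations < 1.0 / self.alpha:
            raise ValueError("n_permutations must be >= 1/alpha")


@dataclass
class Segment:
    trio: Trio | None
    region: GenomicInterval | None
    bin_start_index: int  # inclusive, into the track's bin list
    bin_end_index: int    # inclusive
    n_bins: int
    mean_d: float
    interval: GenomicInterval


def _arc_indices(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All arc boundaries (i, j), 0 <= i < j <= n, with both the arc
    x[i:j] and its complement at least ``min_width`` long."""
    i_all, j_all = np.triu_indices(n + 1, k=min_width)
    keep = (j_all - i_all) <= n - min_width
    return i_all[keep], j_all[keep]


def _max_arc_stat(s: np.ndarray, n: int, i_idx: np.ndarray,
                  j_idx: np.ndarray) -> tuple[float, int, int]:
    """Max over arcs of |mean(arc) - mean(complement)| / sqrt(1/k + 1/(n-k)).

    ``s`` is the cumulative sum with leading zero, length n+1.  The
    common scale factor (the segment SD) is omitted — it is invariant
    under both the arc choice and permutation.  Leftmost (i, then j)
    wins ties.
    """
    k = j_idx - i_idx
    arc = s[j_idx] - s[i_idx]
    total = s[n]
    diff = arc / k - (total - arc) / (n - k)
    stat = np.abs(diff) / np.sqrt(1.0 / k + 1.0 / (n - k))
    best = int(np.argmax(stat))  # argmax returns the first max; triu order
    return float(stat[best]), int(i_idx[best]), int(j_idx[best])


def _block_max_stats(xs: np.ndarray, ks: np.ndarray, w1k: np.ndarray,
                     t2k: np.ndarray) -> np.ndarray:
    """Column-wise max arc statistics for an (n, B) block of permuted data.

    Uses the identity |mean(arc) - mean(comp)| / sqrt(1/k + 1/(n-k)) =
    |arc_sum * w1 - total * w2| with w1 = sqrt(1/k + 1/(n-k)) and
    w2 = (1/(n-k)) / w1.  The total is permutation-invariant, so
    ``t2k = total * w2`` is precomputed per arc length; for each arc
    length only the sliding-window max and min of the arc sums can attain
    the maximum absolute value, giving an O(n) pass per length instead of
    one per arc.
    """
    s = np.vstack([np.zeros((1, xs.shape[1])), np.cumsum(xs, axis=0)])
    out = np.zeros(xs.shape[1])
    for ki, k in enumerate(ks):
        d = s[k:] - s[:-k]
        hi = d.max(axis=0) * w1k[ki] - t2k[ki]
        lo = d.min(axis=0) * w1k[ki] - t2k[ki]
        np.maximum(out, np.abs(hi), out=out)
        np.maximum(out, np.abs(lo), out=out)
    return out


def cbs_max_statistic(x: Sequence[float],
                      min_width: int = 3) -> tuple[int, int, float]:
    """Best circular-arc split of ``x``.

    Returns ``(i, j, t)`` where the arc is ``x[i:j]`` (half-open) and
    ``t`` is the two-sample t statistic (using the sequence's overall
    SD) between arc and complement, maximized in absolute value subject
    to both parts having at least ``min_width`` elements.  A
    zero-variance input yields ``(0, 0, 0.0)`` — no candidate.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * min_width:
        raise ValueError(f"need at least {2 * min_width} values")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return 0, 0, 0.0
    i_idx, j_idx = _arc_indices(n, min_width)
    s = np.concatenate([[0.0], np.cumsum(x)])
    stat, i, j = _max_arc_stat(s, n, i_idx, j_idx)
    return i, j, stat / sd


def _permutation_significant(x: np.ndarray, observed: float,
                             config: CBSConfig,
                             rng: np.random.Generator) -> bool:
    """Is the permutation p-value of ``observed`` at most alpha?

    Stops as soon as the exceedance count rules significance out.
    """
    n = x.size
    mw = config.min_width
    ks = np.arange(mw, n - mw + 1)
    w1k = np.sqrt(1.0 / ks + 1.0 / (n - ks))
    t2k = float(x.sum()) / ((n - ks) * w1k)
    allowed = int(np.floor(config.alpha * config.n_permutations))
    exceed = 0
    done = 0
    # small first blocks: null segments are refuted after a handful of
    # permutations, only genuine change points pay for the full count
    block = 32
    max_block = max(32, min(1024, int(2_000_000 / max(1, n))))
    while done < config.n_permutations:
        b = min(block, config.n_permutations - done)
        perm = rng.permuted(np.broadcast_to(x[:, None], (n, b)).copy(),
                            axis=0)
        stats = _block_max_stats(perm, ks, w1k, t2k)
        exceed += int(np.count_nonzero(stats >= observed))
        done += b
        if exceed > allowed:
            return False
        block = min(block * 2, max_block)
    return True


def cbs_segment(x: Sequence[float], config: CBSConfig | None = None,
                rng: np.random.Generator | None = None
                ) -> list[tuple[int, int, float]]:
    """Segment ``x`` by recursive CBS with permutation p-values.

    Returns ``(start, end, mean)`` tuples with half-open index ranges
    that tile ``0..len(x)``.  A candidate split whose arc would leave a
    flank shorter than ``min_width`` has that boundary snapped to the
    segment edge; sd-undo pruning is applied to the final segmentation.
    """
    config = config or CBSConfig()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    x = np.asarray(x, dtype=float)
    n = x.size
    mw = config.min_width

    boundaries: list[int] = [0, n]

    def split(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        m = hi - lo
        if m < 2 * mw:
            return
        if float(np.std(seg, ddof=1)) == 0.0:
            return
        i_idx, j_idx = _arc_indices(m, mw)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        observed, i, j = _max_arc_stat(s, m, i_idx, j_idx)
        if not _permutation_significant(seg, observed, config, rng):
            return
        # snap boundaries that would strand a short flank
        if 0 < i < mw:
            i = 0
        if m - mw < j < m:
            j = m
        cuts = sorted({i, j} - {0, m})
        if not cuts:
            return
        pts = [0] + cuts + [m]
        for a, b in zip(pts, pts[1:]):
            boundaries.append(lo + a)
            boundaries.append(lo + b)
        for a, b in zip(pts, pts[1:]):
            split(lo + a, lo + b)

    if n >= 2 * mw:
        split(0, n)
    pts = sorted(set(boundaries))
    segments = [(a, b, float(x[a:b].mean())) for a, b in zip(pts, pts[1:])]
    return sd_undo(segments, x, config.undo_sd)


def robust_sd(x: np.ndarray) -> float:
    """Noise SD from the MAD of lag-1 differences, Gaussian-consistent.

    Robust to the change points themselves: a few large jumps barely
    move the median absolute lag-1 difference.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    d = np.diff(x)
    mad = float(np.median(np.abs(d - np.median(d))))
    return 1.4826 * mad / np.sqrt(2.0)


def sd_undo(segments: list[tuple[int, int, float]], x: Sequence[float],
            undo_sd: float) -> list[tuple[int, int, float]]:
    """Merge adjacent segments whose mean difference is < ``undo_sd`` SDs.

    Greedy: repeatedly merge the adjacent pair with the smallest
    |mean difference| / SD while that ratio is below the threshold.  The
    SD is estimated once, robustly, from ``x``.
    """
    x = np.asarray(x, dtype=float)
    segs = list(segments)
    if len(segs) < 2 or undo_sd <= 0:
        return segs
    sd = robust_sd(x)

    def ratio(a, b) -> float:
        dm = abs(a[2] - b[2])
        if sd == 0.0:
            return 0.0 if dm == 0.0 else np.inf
        return dm / sd

    while len(segs) > 1:
        ratios = [ratio(a, b) for a, b in zip(segs, segs[1:])]
        k = int(np.argmin(ratios))
        if ratios[k] >= undo_sd:
            break
        a, b = segs[k], segs[k + 1]
        merged = (a[0], b[1], float(x[a[0]:b[1]].mean()))
        segs[k:k + 2] = [merged]
    return segs


def group_bins_by_region(bins: Sequence,
                         regions: Sequence[GenomicInterval]
                         ) -> list[tuple[GenomicInterval, list[int]]]:
    """Assign bin indices to the targeted region containing them.

    Bins falling in no region are grouped into per-chromosome remainder
    groups so nothing is silently dropped.
    """
    groups: list[tuple[GenomicInterval, list[int]]] = [(r, []) for r in regions]
    leftover: dict[str, list[int]] = {}
    for k, b in enumerate(bins):
        iv = _as_interval(b)
        for r, idx in groups:
            if r.chrom == iv.chrom and r.start <= iv.start and iv.end <= r.end:
                idx.append(k)
                break
        else:
            leftover.setdefault(iv.chrom, []).append(k)
    out = [(r, idx) for r, idx in groups if idx]
    for chrom, idx in leftover.items():
        ivs = [_as_interval(bins[k]) for k in idx]
        out.append((GenomicInterval(chrom, min(i.start for i in ivs),
                                    max(i.end for i in ivs)), idx))
    return out


def segment_md_track(track: MinimumDistanceTrack,
                     regions: Sequence[GenomicInterval],
                     config: CBSConfig | None = None) -> list[Segment]:
    """CBS of a trio's minimum distances, independently per region.

    Each region's segmentation uses a generator freshly seeded from
    ``config.rng_seed``, so per-region results do not depend on the
    order regions are processed in.
    """
    config = config or CBSConfig()
    out: list[Segment] = []
    for region, idx in group_bins_by_region(track.bins, regions):
        d = track.d[np.asarray(idx)]
        if d.size < 2 * config.min_width:
            segs = [(0, d.size, float(d.mean()))] if d.size else []
        else:
            rng = np.random.default_rng(config.rng_seed)
            segs = cbs_segment(d, config, rng)
        for a, b, mean in segs:
            first = _as_interval(track.bins[idx[a]])
            last = _as_interval(track.bins[idx[b - 1]])
            out.append(Segment(
                trio=track.trio, region=region,
                bin_start_index=idx[a], bin_end_index=idx[b - 1],
                n_bins=b - a, mean_d=mean,
                interval=GenomicInterval(first.chrom, first.start, last.end)))
    return out
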