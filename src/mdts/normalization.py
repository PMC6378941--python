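"""Raw counts -> M scores.

M scores are relative copy-number measures per bin per sample: roughly 0
for copy-neutral DNA and -1 for a single-copy (heterozygous) deletion.
They are obtained from the bins-by-samples count matrix by

1. ``log2(count + 1)`` to reduce skew,
2. centering by the column (sample) medians and then the row (bin)
   medians — one pass each, in that order,
3. per-sample loess adjustment against bin GC content, then against bin
   mappability, subtracting each fit.

Bins excluded by QC must not enter this module (they would distort the
medians); the pipeline filters them first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

MIN_BINS_FOR_LOESS = 10


@dataclass
class MScoreMatrix:
    bins: list
    samples: list[str]
    m: np.ndarray  # (n_bins, n_samples)

    def to_tsv(self, path) -> None:
        import pandas as pd
        from .genomic_io import _as_interval
        ivs = [_as_interval(b) for b in self.bins]
        df = pd.DataFrame({"chrom": [iv.chrom for iv in ivs],
                           "start": [iv.start for iv in ivs],
                           "end": [iv.end for iv in ivs]})
        for k, s in enumerate(self.samples):
            df[s] = self.m[:, k]
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def log_transform(counts: np.ndarray) -> np.ndarray:
    """Elementwise log2(count + 1)."""
    counts = np.asarray(counts)
    if counts.size and counts.min() < 0:
        raise ValueError("negative counts")
    return np.log2(counts.astype(float) + 1.0)


def median_center(x: np.ndarray) -> np.ndarray:
    """Subtract sample-column medians, then bin-row medians (one pass each)."""
    x = np.asarray(x, dtype=float)
    x = x - np.median(x, axis=0, keepdims=True)
    x = x - np.median(x, axis=1, keepdims=True)
    return x


def _loess_residual(y: np.ndarray, x: np.ndarray, span: float) -> np.ndarray:
    """y minus its lowess fit on x; identity if x is (near-)constant."""
    rng_x = x.max() - x.min()
    if rng_x < 1e-9 or np.std(x) < 1e-9:
        return y
    fit = lowess(y, x, frac=span, return_sorted=False,
                 delta=0.01 * rng_x)
    return y - fit


def covariate_adjust(x: np.ndarray, bins: Sequence,
                     loess_span: float = 0.75,
                     columns: Sequence[int] | None = None) -> np.ndarray:
    """Remove GC and mappability trends per sample by sequential loess.

    For each sample column, a loess of score vs bin GC is fitted and
    subtracted, then the same against bin mappability.  With fewer than
    10 bins the fit is unstable and adjustment is skipped (warning).

    ``columns`` optionally restricts the adjustment to a subset of sample
    columns (other columns are returned centered-only); each sample's
    adjustment depends only on its own column, so the restricted result
    equals the corresponding columns of the full one.
    """
    x = np.asarray(x, dtype=float).copy()
    if x.shape[0] < MIN_BINS_FOR_LOESS:
        warnings.warn(f"only {x.shape[0]} bins; skipping loess adjustment")
        return x
    gc = np.array([b.gc for b in bins], dtype=float)
    mp = np.array([b.mappability for b in bins], dtype=float)
    cols = range(x.shape[1]) if columns is None else columns
    for j in cols:
        y = x[:, j]
        y = _loess_residual(y, gc, loess_span)
        y = _loess_residual(y, mp, loess_span)
        x[:, j] = y
    return x


def normalize_counts(counts: np.ndarray, bins: Sequence,
                     samples: Sequence[str],
                     loess_span: float = 0.75,
                     loess_columns: Sequence[int] | None = None) -> MScoreMatrix:
    """Full normalization: log2(count+1), median centering, loess."""
    x = median_center(log_transform(counts))
    m = covariate_adjust(x, bins, loess_span, columns=loess_columns)
    return MScoreMatrix(list(bins), list(samples), m)
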