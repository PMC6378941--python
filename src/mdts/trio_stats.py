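"""Per-trio minimum distances and family-level quality control.

At each bin the offspring-minus-father and offspring-minus-mother
M-score differences are computed, and the minimum distance ``d`` is the
one of smaller absolute value:

    delta_F = M_O - M_F,   delta_M = M_O - M_M,
    d = argmin_{delta in {delta_F, delta_M}} |delta|

A deletion inherited from one parent cancels in the difference to that
parent, so |d| ~ 0; only events absent from both parents — de novo —
push d toward -1.  Ties (|delta_F| == |delta_M|) resolve to delta_F.

Families whose minimum-distance track is too noisy or too auto-correlated
(lag-10 autocorrelation > 0.4 or variance > 0.05) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .normalization import MScoreMatrix

LAG = 10
MAX_LAG10_AUTOCORRELATION = 0.4
MAX_VARIANCE = 0.05


@dataclass(frozen=True)
class Trio:
    family_id: str
    offspring_id: str
    father_id: str
    mother_id: str

    def __post_init__(self) -> None:
        ids = {self.offspring_id, self.father_id, self.mother_id}
        if len(ids) != 3:
            raise ValueError(f"trio {self.family_id}: member ids not distinct")

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.offspring_id, self.father_id, self.mother_id)


@dataclass
class MinimumDistanceTrack:
    trio: Trio
    bins: list
    delta_f: np.ndarray
    delta_m: np.ndarray
    d: np.ndarray
    bin_indices: np.ndarray | None = None  # indices into the source M matrix


@dataclass
class FamilyQCStats:
    trio: Trio
    lag10_autocorrelation: float
    variance: float
    passed: bool
    reason: str = ""


def read_pedigree(path) -> pd.DataFrame:
    """Pedigree TSV with columns family_id, offspring, father, mother.

    Optional extra columns (e.g. batch labels or lab QC flags) are kept.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "offspring", "father", "mother"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pedigree is missing columns: {sorted(missing)}")
    return df


def trios_from_pedigree(df: pd.DataFrame) -> list[Trio]:
    return [Trio(r.family_id, r.offspring, r.father, r.mother)
            for r in df.itertuples()]


def minimum_distance(m_offspring: float, m_father: float,
                     m_mother: float) -> float:
    """The minimum distance at a single bin (tie -> father difference)."""
    delta_f = m_offspring - m_father
    delta_m = m_offspring - m_mother
    return delta_f if abs(delta_f) <= abs(delta_m) else delta_m


def compute_md_track(mscores: MScoreMatrix, trio: Trio) -> MinimumDistanceTrack:
    """Per-bin minimum distances for a trio.

    Bins where any member's M score is non-finite are masked and dropped
    from the track (the bin list shrinks accordingly).
    """
    for sid in trio.members:
        if sid not in mscores.samples:
            raise KeyError(f"sample {sid!r} not in M-score matrix")
    cols = [mscores.samples.index(s) for s in trio.members]
    mo, mf, mm = (mscores.m[:, c] for c in cols)
    finite = np.isfinite(mo) & np.isfinite(mf) & np.isfinite(mm)
    mo, mf, mm = mo[finite], mf[finite], mm[finite]
    delta_f = mo - mf
    delta_m = mo - mm
    d = np.where(np.abs(delta_f) <= np.abs(delta_m), delta_f, delta_m)
    bins = [b for b, ok in zip(mscores.bins, finite) if ok]
    return MinimumDistanceTrack(trio, bins, delta_f, delta_m, d,
                                bin_indices=np.flatnonzero(finite))


def lag_autocorrelation(x: np.ndarray, lag: int = LAG) -> float:
    """Biased sample autocorrelation at ``lag``; 0 for a constant series."""
    x = np.asarray(x, dtype=float)
    if x.size <= lag:
        raise ValueError(f"need more than {lag} observations")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        return 0.0
    return float(np.dot(xc[:-lag], xc[lag:]) / denom)


def family_qc(track: MinimumDistanceTrack,
              max_acf: float = MAX_LAG10_AUTOCORRELATION,
              max_var: float = MAX_VARIANCE) -> FamilyQCStats:
    """Family-level QC on the concatenated, genomically ordered d track."""
    d = np.asarray(track.d, dtype=float)
    if d.size <= LAG:
        return FamilyQCStats(track.trio, float("nan"), float("nan"), False,
                             reason=f"fewer than {LAG + 1} bins; "
                                    "lag-10 autocorrelation undefined")
    acf = lag_autocorrelation(d, LAG)
    var = float(np.var(d, ddof=1))
    passed = (acf <= max_acf) and (var <= max_var)
    reason = "" if passed else (
        f"lag10 autocorrelation {acf:.3f} > {max_acf}" if acf > max_acf else ""
    ) + ("" if var <= max_var else f" variance {var:.4f} > {max_var}")
    return FamilyQCStats(track.trio, acf, var, passed, reason.strip())
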