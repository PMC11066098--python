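"""Insulation-score TAD calling.

TAD boundaries are local minima of the insulation profile — the mean
contact count in a sliding square window crossing each bin, expressed as
log2 of its ratio to the chromosome-wide mean.  Boundary strength is the
depth of the minimum below its flanking local maxima; domains tile the
chromosome between consecutive boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ContactMatrix

__all__ = [
    "TADSet",
    "insulation_score",
    "call_boundaries",
    "boundaries_to_tads",
    "tad_stats",
    "call_tads",
]


@dataclass(frozen=True)
class TAD:
    start_bin: int
    end_bin: int      # half-open
    left_strength: float
    right_strength: float

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


@dataclass
class TADSet:
    """Called domains for one chromosome: sorted, non-overlapping, tiling."""

    chrom: str
    bin_size: int
    tads: list[TAD]
    insulation: np.ndarray | None = None

    @property
    def boundaries(self) -> list[int]:
        """All boundary bins, chromosome ends included."""
        if not self.tads:
            return []
        b = [self.tads[0].start_bin]
        b.extend(t.end_bin for t in self.tads)
        return b

    @property
    def internal_boundaries(self) -> list[int]:
        return self.boundaries[1:-1]

    def to_bed(self, path) -> None:
        pd.DataFrame({
            "chrom": self.chrom,
            "start": [t.start_bin * self.bin_size for t in self.tads],
            "end": [t.end_bin * self.bin_size for t in self.tads],
            "name": [f"tad_{k}" for k in range(len(self.tads))],
            "score": [min(t.left_strength, t.right_strength) for t in self.tads],
            "strand": ".",
        }).to_csv(path, sep="\t", header=False, index=False, float_format="%.4g")


def insulation_score(cm: ContactMatrix, window_bins: int = 5,
                     max_masked_frac: float = 0.5) -> np.ndarray:
    """Per-bin insulation: log2 of the sliding-square mean over its
    chromosome-wide mean.

    For bin i the square is [i-w, i) x (i, i+w].  NaN within ``window_bins``
    of the chromosome ends and where the square contains more than
    ``max_masked_frac`` masked cells.
    """
    if cm.state != "balanced":
        raise ValueError(f"insulation_score requires state='balanced', got {cm.state!r}")
    w = int(window_bins)
    n = cm.n_bins
    if w < 2:
        raise ValueError("window_bins must be >= 2")
    if 2 * w >= n:
        raise ValueError(f"window {w} too large for chromosome with {n} bins")
    raw = np.full(n, np.nan)
    cell_ok = np.outer(cm.mask, cm.mask)
    for i in range(w, n - w):
        sq = cm.values[i - w:i, i + 1:i + w + 1]
        ok = cell_ok[i - w:i, i + 1:i + w + 1]
        if ok.mean() < (1.0 - max_masked_frac) or not cm.mask[i]:
            continue
        raw[i] = sq[ok].mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_stat = np.nanmean(raw)
        if not np.isfinite(mean_stat) or mean_stat <= 0:
            return np.full(n, np.nan)
        ins = np.log2(raw / mean_stat)
    return ins


def _local_extrema(x: np.ndarray):
    """Indices of strict-or-plateau local minima and maxima of a profile
    with NaNs treated as segment breaks.  Plateaus report their lowest
    index (deterministic tie-break)."""
    minima, maxima = [], []
    n = len(x)
    i = 0
    while i < n:
        if not np.isfinite(x[i]):
            i += 1
            continue
        j = i
        while j + 1 < n and np.isfinite(x[j + 1]) and x[j + 1] == x[i]:
            j += 1
        left = x[i - 1] if i > 0 and np.isfinite(x[i - 1]) else None
        right = x[j + 1] if j + 1 < n and np.isfinite(x[j + 1]) else None
        if left is not None and right is not None:
            if x[i] < left and x[i] < right:
                minima.append(i)
            elif x[i] > left and x[i] > right:
                maxima.append(i)
        i = j + 1
    return minima, maxima


def call_boundaries(insulation: np.ndarray, delta_thresh: float = 0.2):
    """Boundary candidates from an insulation profile.

    A boundary is a local minimum whose strength — mean of the nearest
    flanking local maxima minus the minimum value — reaches
    ``delta_thresh``.  Returns a list of (bin, strength) sorted by bin.
    """
    minima, maxima = _local_extrema(insulation)
    if not minima:
        return []
    maxima_arr = np.asarray(maxima)
    out = []
    for m in minima:
        if maxima_arr.size:
            left_max = maxima_arr[maxima_arr < m]
            right_max = maxima_arr[maxima_arr > m]
            flank_vals = []
            if left_max.size:
                flank_vals.append(insulation[left_max[-1]])
            if right_max.size:
                flank_vals.append(insulation[right_max[0]])
        else:
            flank_vals = []
        if not flank_vals:
            continue
        strength = float(np.mean(flank_vals) - insulation[m])
        if strength >= delta_thresh:
            out.append((m, strength))
    return out


def boundaries_to_tads(boundaries, n_bins: int, chrom: str = "chr",
                       bin_size: int = 100_000, min_tad_bins: int = 3,
                       insulation: np.ndarray | None = None) -> TADSet:
    """Tile the chromosome into TADs between consecutive boundaries.

    Chromosome ends act as implicit boundaries.  Gaps shorter than
    ``min_tad_bins`` are merged into the weaker-boundary neighbor: of the
    two boundaries delimiting a short TAD, the weaker one is dropped
    (ties broken toward the lower bin index).
    """
    bl = sorted(boundaries)
    if not bl:
        warnings.warn("empty boundary list: returning single whole-chromosome TAD",
                      stacklevel=2)
    END = float("inf")   # chromosome ends are unremovable
    pts = [(0, END)] + [(int(b), float(s)) for b, s in bl if 0 < b < n_bins] + [(n_bins, END)]
    # iteratively drop the weaker delimiter of any too-short TAD
    changed = True
    while changed and len(pts) > 2:
        changed = False
        for k in range(len(pts) - 1):
            if pts[k + 1][0] - pts[k][0] < min_tad_bins:
                ls, rs = pts[k][1], pts[k + 1][1]
                if ls == END and rs == END:
                    continue
                # drop the weaker; tie -> lower bin index goes
                drop = k if (ls < rs or (ls == rs and ls != END)) else k + 1
                del pts[drop]
                changed = True
                break
    tads = []
    for k in range(len(pts) - 1):
        tads.append(TAD(pts[k][0], pts[k + 1][0],
                        left_strength=pts[k][1] if pts[k][1] != END else float("nan"),
                        right_strength=pts[k + 1][1] if pts[k + 1][1] != END else float("nan")))
    return TADSet(chrom=chrom, bin_size=bin_size, tads=tads, insulation=insulation)


def call_tads(cm: ContactMatrix, window_bins: int = 5, delta_thresh: float = 0.2,
              min_tad_bins: int = 3) -> TADSet:
    """Full insulation -> boundaries -> TADSet pipeline for one matrix."""
    ins = insulation_score(cm, window_bins=window_bins)
    bounds = call_boundaries(ins, delta_thresh=delta_thresh)
    return boundaries_to_tads(bounds, cm.n_bins, chrom=cm.chrom,
                              bin_size=cm.bin_size, min_tad_bins=min_tad_bins,
                              insulation=ins)


def tad_stats(tadset: TADSet) -> dict:
    """Count and size distribution (bp) of a TADSet."""
    sizes = np.array([t.n_bins * tadset.bin_size for t in tadset.tads], dtype=float)
    return {
        "count": len(tadset.tads),
        "sizes_bp": sizes,
        "median_size_bp": float(np.median(sizes)) if len(sizes) else float("nan"),
        "mean_size_bp": float(sizes.mean()) if len(sizes) else float("nan"),
    }
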