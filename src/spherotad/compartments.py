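"""A/B compartment calling, orientation, transition regions and metagenes.

Compartments are read from the first eigenvector of the Pearson-correlation
matrix of the observed/expected contact map: the sign of the eigenvector
partitions bins into the active A (+) and inactive B (-) classes.  Because
the eigenvector sign is arbitrary, tracks are oriented against an external
activity reference (gene density or H3K27ac coverage) before any
between-condition comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .matrix import ContactMatrix

__all__ = [
    "CompartmentTrack",
    "TransitionRegion",
    "compartment_eigenvector",
    "orient_track",
    "call_transitions",
    "gene_ab_score",
    "metagene_ab",
]


@dataclass
class CompartmentTrack:
    """Per-bin first-eigenvector ("A/B score") track for one chromosome."""

    chrom: str
    bin_size: int
    pc1: np.ndarray            # per-bin real, NaN on masked bins
    oriented: bool = False
    score_scale: float = 100.0
    min_abs: float | None = None  # threshold below which label is NA

    def __post_init__(self) -> None:
        self.pc1 = np.asarray(self.pc1, dtype=float)
        if self.min_abs is None:
            self.min_abs = 0.1 * self.score_scale

    @property
    def n_bins(self) -> int:
        return len(self.pc1)

    @property
    def labels(self) -> np.ndarray:
        """Per-bin label in {'A', 'B', 'NA'}."""
        lab = np.full(self.n_bins, "NA", dtype=object)
        ok = np.isfinite(self.pc1) & (np.abs(self.pc1) >= self.min_abs)
        lab[ok & (self.pc1 > 0)] = "A"
        lab[ok & (self.pc1 < 0)] = "B"
        return lab

    def to_bedgraph(self, path) -> None:
        ok = np.isfinite(self.pc1)
        idx = np.nonzero(ok)[0]
        pd.DataFrame({
            "chrom": self.chrom,
            "start": idx * self.bin_size,
            "end": (idx + 1) * self.bin_size,
            "value": self.pc1[idx],
        }).to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


@dataclass(frozen=True)
class TransitionRegion:
    """Maximal run of bins flipping compartment in the same direction."""

    start_bin: int
    end_bin: int   # half-open
    kind: str      # 'AtoB' or 'BtoA'

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


def compartment_eigenvector(cm: ContactMatrix, score_scale: float = 100.0,
                            min_unmasked: int = 10) -> CompartmentTrack:
    """First eigenvector of the O/E correlation matrix (unoriented).

    The correlation matrix is computed column-wise over unmasked bins; the
    eigenvector of its largest eigenvalue, normalized to unit length and
    multiplied by ``score_scale``, is the per-bin compartment score.  Masked
    bins carry NaN.  A degenerate (constant-column) correlation matrix
    yields an all-NaN track with a warning.
    """
    if cm.state != "oe":
        raise ValueError(f"compartment_eigenvector requires state='oe', got {cm.state!r}")
    mask = cm.mask & np.isfinite(cm.values).any(axis=1)
    if mask.sum() < min_unmasked:
        raise ValueError(f"need at least {min_unmasked} unmasked bins")
    sub = cm.values[np.ix_(mask, mask)]
    # column-wise fill of residual NaNs with the column mean keeps corrcoef defined
    col_mean = np.nanmean(sub, axis=0)
    nan_pos = np.isnan(sub)
    if nan_pos.any():
        sub = np.where(nan_pos, np.broadcast_to(col_mean, sub.shape), sub)
    sd = sub.std(axis=0)
    pc1 = np.full(cm.n_bins, np.nan)
    if np.any(sd == 0) and np.all(sd == 0):
        warnings.warn("degenerate O/E matrix (constant columns); returning all-NA track",
                      stacklevel=2)
        return CompartmentTrack(cm.chrom, cm.bin_size, pc1, score_scale=score_scale)
    keep = sd > 0
    if not keep.all():
        sub = sub[np.ix_(keep, keep)]
    corr = np.corrcoef(sub, rowvar=False)
    w, v = linalg.eigh(corr, subset_by_index=[corr.shape[0] - 1, corr.shape[0] - 1])
    vec = v[:, 0]
    vec = vec / np.linalg.norm(vec) * score_scale
    full_idx = np.nonzero(mask)[0][keep]
    pc1[full_idx] = vec
    # the NA threshold tracks the typical score magnitude (RMS), not the
    # nominal scale, so it stays meaningful at any bin count
    min_abs = 0.1 * float(np.sqrt(np.mean(vec ** 2)))
    return CompartmentTrack(cm.chrom, cm.bin_size, pc1, score_scale=score_scale,
                            min_abs=min_abs)


def orient_track(track: CompartmentTrack, reference: np.ndarray) -> CompartmentTrack:
    """Fix the eigenvector sign against an activity reference.

    Flips the track iff its correlation with ``reference`` (e.g. per-bin
    gene density or H3K27ac coverage) is negative.  Idempotent: orienting
    an oriented track leaves it unchanged.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.shape != track.pc1.shape:
        raise ValueError("reference must cover the same bins as the track")
    ok = np.isfinite(track.pc1) & np.isfinite(ref)
    if ok.sum() < 3 or ref[ok].std() == 0:
        raise ValueError("reference has zero variance over unmasked bins")
    r = np.corrcoef(track.pc1[ok], ref[ok])[0, 1]
    pc1 = -track.pc1 if r < 0 else track.pc1.copy()
    return replace(track, pc1=pc1, oriented=True)


def call_transitions(track_a: CompartmentTrack, track_b: CompartmentTrack,
                     min_abs: float | None = None):
    """Compartment transition regions between two conditions.

    A transition bin has |pc1| >= ``min_abs`` in both conditions and
    opposite A/B labels; maximal runs of same-direction transition bins are
    merged into regions.  Returns ``(regions, counts)`` where counts maps
    'AtoB'/'BtoA' to region counts (condition a -> condition b direction).
    """
    if not (track_a.oriented and track_b.oriented):
        raise ValueError("tracks must be oriented before calling transitions")
    if track_a.n_bins != track_b.n_bins:
        raise ValueError("tracks must share the same bin table")
    if min_abs is None:
        min_abs = track_a.min_abs
    a, b = track_a.pc1, track_b.pc1
    ok = (np.isfinite(a) & np.isfinite(b)
          & (np.abs(a) >= min_abs) & (np.abs(b) >= min_abs))
    direction = np.zeros(track_a.n_bins, dtype=int)   # +1 AtoB, -1 BtoA
    direction[ok & (a > 0) & (b < 0)] = 1
    direction[ok & (a < 0) & (b > 0)] = -1

    regions: list[TransitionRegion] = []
    i, n = 0, len(direction)
    while i < n:
        if direction[i] == 0:
            i += 1
            continue
        j = i
        while j < n and direction[j] == direction[i]:
            j += 1
        regions.append(TransitionRegion(i, j, "AtoB" if direction[i] == 1 else "BtoA"))
        i = j
    counts = {"AtoB": sum(r.kind == "AtoB" for r in regions),
              "BtoA": sum(r.kind == "BtoA" for r in regions)}
    return regions, counts


def gene_ab_score(track: CompartmentTrack, genes: pd.DataFrame) -> pd.Series:
    """Per-gene compartment score = pc1 of the bin containing the gene's TSS.

    Genes whose TSS falls outside the bin table are dropped with a warning.
    """
    tss_bin = (genes["tss"] // track.bin_size).astype(int)
    inside = (tss_bin >= 0) & (tss_bin < track.n_bins)
    n_dropped = int((~inside).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} genes outside bin table dropped", stacklevel=2)
    scores = pd.Series(track.pc1[tss_bin[inside]], index=genes.index[inside],
                       name="ab_score")
    return scores


def _rescale_body(values: np.ndarray, n_out: int) -> np.ndarray:
    """Average a 1-D signal into n_out equal-width windows (fractional bins
    weighted by coverage)."""
    n_in = len(values)
    edges = np.linspace(0, n_in, n_out + 1)
    out = np.empty(n_out)
    for k in range(n_out):
        lo, hi = edges[k], edges[k + 1]
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
        idx = np.arange(i0, min(i1, n_in))
        w = np.minimum(idx + 1, hi) - np.maximum(idx, lo)
        v = values[idx]
        good = np.isfinite(v) & (w > 0)
        out[k] = np.average(v[good], weights=w[good]) if good.any() else np.nan
    return out


def metagene_ab(track_a: CompartmentTrack, track_b: CompartmentTrack,
                genes: pd.DataFrame, n_body_bins: int = 20,
                flank_bins: int = 10, paired: bool = True) -> dict:
    """Metagene compartment-score profiles over a gene set, both conditions.

    Each gene body is rescaled to ``n_body_bins`` positions with
    ``flank_bins`` genomic bins of flank on each side (strand-oriented).
    Returns per-position mean profiles, per-gene heatmap matrices, and a
    two-tailed t-test of per-gene mean body score between conditions
    (paired by default, since the same genes are scored in both).
    """
    if genes.empty:
        raise ValueError("gene_set is empty")
    width = n_body_bins + 2 * flank_bins
    rows_a, rows_b, kept = [], [], []
    for gid, g in genes.iterrows():
        b0 = int(g["start"] // track_a.bin_size)
        b1 = int(g["end"] // track_a.bin_size) + 1
        lo, hi = b0 - flank_bins, b1 + flank_bins
        if lo < 0 or hi > track_a.n_bins or b1 <= b0:
            continue
        prof_a = np.concatenate([track_a.pc1[lo:b0],
                                 _rescale_body(track_a.pc1[b0:b1], n_body_bins),
                                 track_a.pc1[b1:hi]])
        prof_b = np.concatenate([track_b.pc1[lo:b0],
                                 _rescale_body(track_b.pc1[b0:b1], n_body_bins),
                                 track_b.pc1[b1:hi]])
        if g.get("strand", "+") == "-":
            prof_a, prof_b = prof_a[::-1], prof_b[::-1]
        rows_a.append(prof_a)
        rows_b.append(prof_b)
        kept.append(gid)
    mat_a = np.array(rows_a).reshape(-1, width)
    mat_b = np.array(rows_b).reshape(-1, width)
    body = slice(flank_bins, flank_bins + n_body_bins)
    mean_a = np.nanmean(mat_a[:, body], axis=1) if len(kept) else np.array([])
    mean_b = np.nanmean(mat_b[:, body], axis=1) if len(kept) else np.array([])
    if len(kept) >= 2:
        if paired:
            t, p = stats.ttest_rel(mean_b, mean_a, nan_policy="omit")
        else:
            t, p = stats.ttest_ind(mean_b, mean_a, equal_var=False, nan_policy="omit")
        stat, pval = float(t), float(p)
    else:
        stat, pval = float("nan"), float("nan")
    delta = float(np.nanmean(mean_b) - np.nanmean(mean_a)) if len(kept) else float("nan")
    return {
        "profile_a": np.nanmean(mat_a, axis=0) if len(kept) else np.full(width, np.nan),
        "profile_b": np.nanmean(mat_b, axis=0) if len(kept) else np.full(width, np.nan),
        "heatmap_a": mat_a,
        "heatmap_b": mat_b,
        "gene_ids": kept,
        "statistic": stat,
        "p_value": pval,
        "delta": delta,
        "direction": "down" if delta < 0 else "up",
        "n_genes": len(kept),
    }
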