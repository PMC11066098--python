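"""Contact-matrix data model, I/O, ICE balancing and O/E normalization.

A :class:`ContactMatrix` holds one chromosome's symmetric cis contact map
at a fixed bin size, together with a per-bin validity mask and a state tag
(``raw`` -> ``balanced`` -> ``oe``).  All matrices are dense numpy arrays;
the package targets desk-scale single-chromosome analyses, not genome-wide
out-of-core storage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContactMatrix",
    "read_contacts",
    "write_contacts",
    "ice_balance",
    "expected_by_distance",
    "observed_over_expected",
    "eigen_correlation",
    "coarsen",
]


@dataclass
class ContactMatrix:
    """Symmetric binned cis contact map for one chromosome.

    Parameters
    ----------
    chrom : chromosome name.
    bin_size : bin width in bp.
    values : (n, n) symmetric nonnegative array.  NaN marks missing cells
        (only in ``oe`` state).
    mask : boolean per-bin validity flag; ``False`` bins are excluded from
        balancing, expected-by-distance and all downstream means.
    state : one of ``raw``, ``balanced``, ``oe``.
    bias : per-bin ICE bias vector (set by :func:`ice_balance`).
    converged : whether balancing reached its tolerance.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    state: str = "raw"
    bias: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.mask is None:
            self.mask = np.ones(self.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_bins,):
                raise ValueError("mask length must equal n_bins")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "ContactMatrix":
        return replace(self, values=self.values.copy(), mask=self.mask.copy(),
                       bias=None if self.bias is None else self.bias.copy())

    def check_symmetric(self, tol: float = 1e-8) -> bool:
        v = np.nan_to_num(self.values)
        return bool(np.allclose(v, v.T, atol=tol))


def _read_bins(bins_path: str | Path) -> tuple[str, int, int]:
    """Parse a BED bin table -> (chrom, bin_size, n_bins).

    The table must be sorted, single-chromosome, constant width except the
    final bin (which may be short).
    """
    bins = pd.read_csv(bins_path, sep="\t", header=None,
                       names=["chrom", "start", "end", "bin_id"],
                       usecols=[0, 1, 2, 3])
    if bins["chrom"].nunique() != 1:
        raise ValueError("bin table must cover a single chromosome")
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    if not np.all(np.diff(starts) > 0):
        raise ValueError("bin table must be sorted by start")
    widths = ends - starts
    if len(widths) > 1 and not np.all(widths[:-1] == widths[0]):
        raise ValueError("inconsistent bin width (only the final bin may be short)")
    if widths[-1] > widths[0]:
        raise ValueError("inconsistent bin width (final bin wider than the rest)")
    return str(bins["chrom"].iloc[0]), int(widths[0]), len(bins)


def read_contacts(triplet_path: str | Path, bins_path: str | Path) -> ContactMatrix:
    """Read a triplet TSV (bin_i, bin_j, count) plus BED bin table.

    Entries may be given in either triangle; they are mirrored into a
    symmetric matrix.  Duplicate (i, j) pairs (after orienting to the upper
    triangle) are an error, not summed.
    """
    chrom, bin_size, n = _read_bins(bins_path)
    trip = pd.read_csv(triplet_path, sep="\t", header=None,
                       names=["bin_i", "bin_j", "count"], comment="#")
    values = np.zeros((n, n), dtype=float)
    if len(trip):
        i = trip["bin_i"].to_numpy(dtype=np.int64)
        j = trip["bin_j"].to_numpy(dtype=np.int64)
        c = trip["count"].to_numpy(dtype=float)
        if i.min(initial=0) < 0 or j.min(initial=0) < 0 or i.max(initial=0) >= n or j.max(initial=0) >= n:
            raise IndexError("triplet bin index out of range for bin table")
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        key = lo * n + hi
        if len(np.unique(key)) != len(key):
            raise ValueError("duplicate (bin_i, bin_j) entries in triplet file")
        values[lo, hi] = c
        values[hi, lo] = c
    return ContactMatrix(chrom=chrom, bin_size=bin_size, values=values, state="raw")


def write_contacts(cm: ContactMatrix, triplet_path: str | Path,
                   bins_path: str | Path | None = None) -> None:
    """Write upper-triangle nonzero cells as triplet TSV (and optionally bins)."""
    iu, ju = np.triu_indices(cm.n_bins)
    v = cm.values[iu, ju]
    keep = v != 0
    df = pd.DataFrame({"bin_i": iu[keep], "bin_j": ju[keep], "count": v[keep]})
    if cm.state == "raw":
        df["count"] = df["count"].astype(np.int64)
    df.to_csv(triplet_path, sep="\t", header=False, index=False)
    if bins_path is not None:
        write_bins(cm.chrom, cm.bin_size, cm.n_bins, bins_path)


def write_bins(chrom: str, bin_size: int, n_bins: int, path: str | Path,
               chrom_length: int | None = None) -> None:
    starts = np.arange(n_bins, dtype=np.int64) * bin_size
    ends = starts + bin_size
    if chrom_length is not None:
        ends[-1] = min(ends[-1], chrom_length)
    pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                  "bin_id": np.arange(n_bins)}).to_csv(
        path, sep="\t", header=False, index=False)


def ice_balance(cm: ContactMatrix, max_iter: int = 200, tol: float = 1e-5,
                min_nnz: int = 10) -> ContactMatrix:
    """Iterative correction (ICE / iterative proportional fitting).

    Bins with fewer than ``min_nnz`` nonzero cells are masked out; the
    remaining submatrix is rescaled so every unmasked row sums to the same
    value (mean marginal 1), iterating until the relative spread of the
    unmasked row sums falls below ``tol``.  Returns a new matrix with
    ``state='balanced'`` and the per-bin bias vector attached.
    """
    if cm.state != "raw":
        raise ValueError(f"ice_balance expects a raw matrix, got state={cm.state!r}")
    values = cm.values.astype(float).copy()
    nnz = (values > 0).sum(axis=1)
    mask = cm.mask & (nnz >= min_nnz)
    if not mask.any():
        raise ValueError("no unmasked bins left after min_nnz filtering")
    values[~mask, :] = 0.0
    values[:, ~mask] = 0.0

    bias = np.ones(cm.n_bins)
    converged = False
    for _ in range(max_iter):
        s = values.sum(axis=1)
        s_valid = s[mask]
        mean_s = s_valid.mean()
        if mean_s == 0:
            raise ValueError("all unmasked rows sum to zero")
        rel = s_valid / mean_s
        if np.abs(rel - 1.0).max() < tol:
            converged = True
            break
        corr = np.ones(cm.n_bins)
        corr[mask] = rel
        values /= np.outer(corr, corr)
        bias *= corr
    # normalize so unmasked row sums are exactly comparable: target sum 1
    s = values[np.ix_(mask, mask)].sum(axis=1)
    scale = s.mean()
    if scale > 0:
        values /= scale
        bias *= np.sqrt(scale)
    if not converged:
        warnings.warn(f"ICE did not converge in {max_iter} iterations; "
                      "returning partial result", stacklevel=2)
    out = ContactMatrix(chrom=cm.chrom, bin_size=cm.bin_size, values=values,
                        mask=mask, state="balanced", bias=bias,
                        converged=converged)
    return out


def expected_by_distance(cm: ContactMatrix) -> np.ndarray:
    """Mean contact per genomic separation over unmasked cells.

    Returns an array ``expected`` of length n_bins where ``expected[d]`` is
    the mean of ``values[i, j]`` over unmasked cell pairs with ``|i-j| = d``;
    NaN where no unmasked pair exists at that distance.
    """
    if cm.state != "balanced":
        raise ValueError(f"expected_by_distance requires state='balanced', got {cm.state!r}")
    n = cm.n_bins
    expected = np.full(n, np.nan)
    mask = cm.mask
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        ok = mask[i] & mask[j]
        if ok.any():
            expected[d] = cm.values[i[ok], j[ok]].mean()
    return expected


def observed_over_expected(cm: ContactMatrix) -> ContactMatrix:
    """Divide out the distance decay: oe[i,j] = values[i,j] / expected[|i-j|].

    Masked bins and distances with zero expected become NaN.
    """
    if cm.state != "balanced":
        raise ValueError(f"observed_over_expected requires state='balanced', got {cm.state!r}")
    n = cm.n_bins
    expected = expected_by_distance(cm)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    exp_mat = expected[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp_mat > 0, cm.values / exp_mat, np.nan)
    oe[~cm.mask, :] = np.nan
    oe[:, ~cm.mask] = np.nan
    return ContactMatrix(chrom=cm.chrom, bin_size=cm.bin_size, values=oe,
                         mask=cm.mask.copy(), state="oe", bias=cm.bias,
                         converged=cm.converged)


def eigen_correlation(track_a, track_b) -> float:
    """Pearson correlation of two compartment eigenvector tracks.

    Operates on jointly unmasked (non-NaN) bins; requires at least 3.
    Accepts CompartmentTrack objects or plain arrays.
    """
    a = np.asarray(getattr(track_a, "pc1", track_a), dtype=float)
    b = np.asarray(getattr(track_b, "pc1", track_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("tracks must share the same bin table")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 jointly unmasked bins")
    r, _ = stats.pearsonr(a[ok], b[ok])
    return float(r)


def coarsen(cm: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum-pool a raw matrix into bins ``factor`` times wider.

    Used to rebin e.g. a 100-kb matrix to 1 Mb before the eigenvector
    correlation check.  A trailing partial bin is retained.
    """
    if cm.state != "raw":
        raise ValueError("coarsen operates on raw matrices")
    n = cm.n_bins
    m = -(-n // factor)
    pad = m * factor - n
    v = np.pad(cm.values, ((0, pad), (0, pad)))
    v = v.reshape(m, factor, m, factor).sum(axis=(1, 3))
    mask = np.pad(cm.mask, (0, pad)).reshape(m, factor).any(axis=1)
    return ContactMatrix(chrom=cm.chrom, bin_size=cm.bin_size * factor,
                         values=v, mask=mask, state="raw")
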