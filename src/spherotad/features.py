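"""Peak/gene integration statistics.

Interval-set overlap accounting with significance, peak density per TAD
change class, TSS metagene profiles, enhancer-to-gene distance tests,
gene-set x TAD-class enrichment, ROSE-style super-enhancer calling with
the tangent-rule cutoff, differential-expression table summarization and
the comparative-Ct ChIP-qPCR fold enrichment.

All coordinates are 0-based half-open (BED convention); the overlap rule
everywhere is "any overlap >= 1 bp".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "PeakSet",
    "SuperEnhancerSet",
    "read_bed",
    "read_gene_table",
    "overlap_peaks",
    "overlap_counts",
    "overlap_significance",
    "peak_density_by_tad_class",
    "tss_metagene",
    "enhancer_distance",
    "call_super_enhancers",
    "assign_se_genes",
    "de_summary",
    "classify_de",
    "chip_qpcr_enrichment",
]


# ---------------------------------------------------------------------------
# containers and I/O

@dataclass
class PeakSet:
    """Named set of scored genomic intervals, kept sorted by (chrom, start)."""

    name: str
    intervals: pd.DataFrame    # columns: chrom, start, end, score

    def __post_init__(self) -> None:
        df = self.intervals
        need = ["chrom", "start", "end"]
        if not all(c in df.columns for c in need):
            raise ValueError("intervals need chrom/start/end columns")
        if "score" not in df.columns:
            df = df.assign(score=0.0)
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        sorted_ok = df.sort_values(["chrom", "start"], kind="stable")
        if not df.index.equals(sorted_ok.index):
            warnings.warn(f"PeakSet {self.name!r} was unsorted; auto-sorting",
                          stacklevel=3)
            df = sorted_ok.reset_index(drop=True)
        self.intervals = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.intervals["start"] + self.intervals["end"]) // 2).to_numpy()

    def tree(self) -> dict[str, IntervalTree]:
        out: dict[str, IntervalTree] = {}
        for chrom, grp in self.intervals.groupby("chrom"):
            out[str(chrom)] = IntervalTree.from_tuples(
                zip(grp["start"], grp["end"]))
        return out

    def to_bed(self, path) -> None:
        df = self.intervals
        pd.DataFrame({
            "chrom": df["chrom"], "start": df["start"], "end": df["end"],
            "name": [f"{self.name}_{k}" for k in range(len(df))],
            "score": df["score"], "strand": ".",
        }).to_csv(path, sep="\t", header=False, index=False, float_format="%.4g")


def read_bed(path, name: str | None = None) -> PeakSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][:df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    keep = df[["chrom", "start", "end"]].copy()
    keep["score"] = df["score"] if "score" in df.columns else 0.0
    return PeakSet(name=name or str(path), intervals=keep)


def read_gene_table(path) -> pd.DataFrame:
    """TSV gene table with header: gene_id, chrom, tss, strand, start, end,
    log2FC, padj, de_class."""
    genes = pd.read_csv(path, sep="\t")
    return genes.set_index("gene_id")


# ---------------------------------------------------------------------------
# overlap accounting

def _truncate2(x: float) -> float:
    return np.trunc(x * 100) / 100


def overlap_peaks(a: PeakSet, b: PeakSet) -> dict:
    """Shared/exclusive accounting between two peak sets (>=1 bp rule).

    Percentages are truncated (not rounded) to two decimals, matching how
    shared fractions are conventionally printed.
    """
    tree_b = b.tree()
    tree_a = a.tree()

    def n_shared(src: PeakSet, trees) -> int:
        cnt = 0
        for row in src.intervals.itertuples(index=False):
            t = trees.get(str(row.chrom))
            if t is not None and t.overlaps(row.start, row.end):
                cnt += 1
        return cnt

    shared_a = n_shared(a, tree_b)
    shared_b = n_shared(b, tree_a)
    return overlap_counts(len(a), len(b), shared_a, shared_b)


def overlap_counts(n_a: int, n_b: int, shared_a: int, shared_b: int | None = None) -> dict:
    """Count-mode overlap accounting from already-tabulated totals."""
    if shared_b is None:
        shared_b = shared_a
    return {
        "n_a": n_a, "n_b": n_b,
        "shared_a": shared_a, "shared_b": shared_b,
        "exclusive_a": n_a - shared_a, "exclusive_b": n_b - shared_b,
        "pct_shared_a": _truncate2(100.0 * shared_a / n_a) if n_a else float("nan"),
        "pct_shared_b": _truncate2(100.0 * shared_b / n_b) if n_b else float("nan"),
    }


def overlap_significance(a: PeakSet, b: PeakSet, universe,
                         method: str = "hypergeometric",
                         n_perm: int = 1000, seed: int = 0) -> dict:
    """Significance of the overlap between two interval sets.

    hypergeometric: the universe (an (start, end) span in bp) is discretized
    into bins of the median peak width; each set is mapped to its set of hit
    bins; the upper-tail hypergeometric p of the intersection size is
    reported, with fold = observed / expected intersection.

    permutation: b's intervals are placed uniformly at random in the
    universe ``n_perm`` times; empirical two-tail p on the shared-peak count
    of a.
    """
    u_start, u_end = int(universe[0]), int(universe[1])
    span = u_end - u_start
    for ps in (a, b):
        iv = ps.intervals
        if (iv["start"] < u_start).any() or (iv["end"] > u_end).any():
            raise ValueError(f"peaks of {ps.name!r} fall outside the universe")
    if method == "hypergeometric":
        widths = np.concatenate([a.intervals["end"] - a.intervals["start"],
                                 b.intervals["end"] - b.intervals["start"]])
        w = max(int(np.median(widths)), 1)
        n_bins = max(span // w, 1)

        def hit_bins(ps: PeakSet) -> set:
            hits: set[int] = set()
            for s, e in zip(ps.intervals["start"], ps.intervals["end"]):
                hits.update(range((s - u_start) // w,
                                  min((e - 1 - u_start) // w + 1, n_bins)))
            return hits

        ha, hb = hit_bins(a), hit_bins(b)
        k = len(ha & hb)
        M, nA, nB = n_bins, len(ha), len(hb)
        expected = nA * nB / M
        fold = k / expected if expected > 0 else float("nan")
        if fold >= 1:
            p = float(stats.hypergeom.sf(k - 1, M, nA, nB))
            tail = "enrichment"
        else:
            p = float(stats.hypergeom.cdf(k, M, nA, nB))
            tail = "depletion"
        return {"observed": k, "expected": expected, "fold": fold, "p": p,
                "tail": tail, "n_universe_bins": M}
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        obs = overlap_peaks(a, b)["shared_a"]
        lens = (b.intervals["end"] - b.intervals["start"]).to_numpy()
        null = np.empty(n_perm)
        a_iv = a.intervals
        for t in range(n_perm):
            starts = rng.integers(u_start, u_end - lens, size=len(lens))
            rb = PeakSet("perm", pd.DataFrame({
                "chrom": b.intervals["chrom"].to_numpy(),
                "start": starts, "end": starts + lens}))
            null[t] = overlap_peaks(a, rb)["shared_a"]
        expected = float(null.mean())
        fold = obs / expected if expected > 0 else float("inf")
        hi = (1 + np.sum(null >= obs)) / (n_perm + 1)
        lo = (1 + np.sum(null <= obs)) / (n_perm + 1)
        p = float(min(1.0, 2 * min(hi, lo)))
        return {"observed": obs, "expected": expected, "fold": fold, "p": p,
                "tail": "enrichment" if fold >= 1 else "depletion"}
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# TAD-class and metagene statistics

def peak_density_by_tad_class(peaks: PeakSet, changes) -> dict:
    """Peaks per Mb inside each change-event interval, by class.

    Returns per-class density arrays (one entry per event) and two-sided
    Mann-Whitney p-values for each class pair; empty classes are NA and
    excluded from tests.
    """
    mids = peaks.midpoints
    mids.sort()
    per_class: dict[str, list[float]] = {}
    for e in changes.events:
        lo = e.start_bin * changes.bin_size
        hi = e.end_bin * changes.bin_size
        n = np.searchsorted(mids, hi) - np.searchsorted(mids, lo)
        mb = (hi - lo) / 1e6
        per_class.setdefault(e.kind, []).append(n / mb if mb > 0 else np.nan)
    densities = {k: np.asarray(v) for k, v in per_class.items()}
    tests = {}
    kinds = [k for k, v in densities.items() if len(v) >= 2]
    for i, ka in enumerate(kinds):
        for kb in kinds[i + 1:]:
            u, p = stats.mannwhitneyu(densities[ka], densities[kb],
                                      alternative="two-sided")
            tests[(ka, kb)] = {"U": float(u), "p": float(p)}
    summary = {k: float(np.nanmean(v)) if len(v) else float("nan")
               for k, v in densities.items()}
    return {"densities": densities, "mean_density": summary, "tests": tests}


def tss_metagene(peaks: PeakSet, genes: pd.DataFrame, flank_bp: int = 5000,
                 bin_bp: int = 100, random_genes: pd.DataFrame | None = None) -> dict:
    """Peak-coverage metagene around TSSs, strand-oriented.

    Coverage is a 0/1 peak-overlap indicator per ``bin_bp`` window in
    [TSS - flank, TSS + flank); minus-strand profiles are reversed so
    downstream is always to the right.  If ``random_genes`` is given, the
    central-window means of the two sets are compared by two-sided
    Mann-Whitney.
    """
    n_pos = 2 * flank_bp // bin_bp
    trees = peaks.tree()

    def profile_matrix(gs: pd.DataFrame) -> np.ndarray:
        mat = np.zeros((len(gs), n_pos))
        for r, (_, g) in enumerate(gs.iterrows()):
            t = trees.get(str(g["chrom"]))
            if t is None:
                continue
            base = int(g["tss"]) - flank_bp
            for k in range(n_pos):
                s = base + k * bin_bp
                if t.overlaps(s, s + bin_bp):
                    mat[r, k] = 1.0
            if g.get("strand", "+") == "-":
                mat[r] = mat[r][::-1]
        return mat

    mat = profile_matrix(genes)
    out = {"profile": mat.mean(axis=0) if len(mat) else np.zeros(n_pos),
           "heatmap": mat,
           "positions_bp": np.arange(n_pos) * bin_bp - flank_bp + bin_bp // 2}
    if random_genes is not None and len(random_genes):
        rmat = profile_matrix(random_genes)
        c0, c1 = n_pos // 2 - 5, n_pos // 2 + 5
        cs, cr = mat[:, c0:c1].mean(axis=1), rmat[:, c0:c1].mean(axis=1)
        if len(cs) >= 2 and len(cr) >= 2 and (cs.std() + cr.std()) > 0:
            u, p = stats.mannwhitneyu(cs, cr, alternative="two-sided")
            out["test"] = {"U": float(u), "p": float(p),
                           "mean_set": float(cs.mean()), "mean_random": float(cr.mean())}
        out["profile_random"] = rmat.mean(axis=0)
    return out


def enhancer_distance(peaks: PeakSet, acetyl: PeakSet, genes: pd.DataFrame,
                      gene_set: pd.DataFrame, n_random: int | None = None,
                      seed: int = 0) -> dict:
    """Distance from enhancer-associated peaks to the nearest gene-set TSS.

    Enhancer peaks are those overlapping the acetylation (H3K27ac) set by
    >=1 bp.  For each enhancer peak the distance is |peak midpoint -
    nearest TSS| within the given gene set, and separately within a
    size-matched random sample of 'ns' genes; the one-sided Mann-Whitney
    tests whether gene-set distances are smaller.
    """
    actree = acetyl.tree()
    is_enh = []
    for row in peaks.intervals.itertuples(index=False):
        t = actree.get(str(row.chrom))
        is_enh.append(t is not None and t.overlaps(row.start, row.end))
    enh = peaks.intervals[np.asarray(is_enh, dtype=bool)]
    if enh.empty:
        warnings.warn("no enhancer-associated peaks (zero acetyl overlap)",
                      stacklevel=2)
        return {"n_enhancers": 0, "dist_set": np.array([]),
                "dist_random": np.array([]), "p": float("nan")}
    mids = ((enh["start"] + enh["end"]) // 2).to_numpy()

    def nearest(tss: np.ndarray) -> np.ndarray:
        tss = np.sort(tss)
        pos = np.searchsorted(tss, mids)
        left = tss[np.clip(pos - 1, 0, len(tss) - 1)]
        right = tss[np.clip(pos, 0, len(tss) - 1)]
        return np.minimum(np.abs(mids - left), np.abs(mids - right))

    rng = np.random.default_rng(seed)
    ns_pool = genes[genes["de_class"] == "ns"] if "de_class" in genes else genes
    k = n_random if n_random is not None else len(gene_set)
    k = min(k, len(ns_pool))
    rand = ns_pool.sample(n=k, replace=False, random_state=int(rng.integers(2**31)))
    d_set = nearest(gene_set["tss"].to_numpy())
    d_rand = nearest(rand["tss"].to_numpy())
    u, p = stats.mannwhitneyu(d_set, d_rand, alternative="less")
    return {"n_enhancers": len(enh), "dist_set": d_set, "dist_random": d_rand,
            "U": float(u), "p": float(p),
            "median_set": float(np.median(d_set)),
            "median_random": float(np.median(d_rand))}


# ---------------------------------------------------------------------------
# super-enhancers

@dataclass
class SuperEnhancerSet:
    """Stitched enhancer regions ranked by total signal, with tangent cutoff."""

    regions: pd.DataFrame      # chrom, start, end, signal, rank, is_super
    cutoff_signal: float
    cutoff_rank: int           # rank index (ascending) where the slope first reaches 1

    @property
    def n_super(self) -> int:
        return int(self.regions["is_super"].sum())

    def supers(self) -> pd.DataFrame:
        return self.regions[self.regions["is_super"]]


def _stitch(intervals: pd.DataFrame, stitch_bp: int) -> pd.DataFrame:
    rows = []
    for chrom, grp in intervals.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur_s, cur_e, cur_sig = None, None, 0.0
        for s, e, sig in zip(grp["start"], grp["end"], grp["score"]):
            if cur_s is None:
                cur_s, cur_e, cur_sig = s, e, sig
            elif s - cur_e <= stitch_bp:
                cur_e, cur_sig = max(cur_e, e), cur_sig + sig
            else:
                rows.append((chrom, cur_s, cur_e, cur_sig))
                cur_s, cur_e, cur_sig = s, e, sig
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, cur_sig))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "signal"])


def tangent_cutoff_index(signal_sorted: np.ndarray) -> int:
    """Index into an ascending signal vector where the slope of the
    rank-vs-signal curve, both axes rescaled to [0, 1], first reaches 1."""
    n = len(signal_sorted)
    y = signal_sorted / signal_sorted.max()
    x = np.arange(n) / (n - 1)
    slopes = np.diff(y) / np.diff(x)
    above = np.nonzero(slopes >= 1.0)[0]
    return int(above[0]) if above.size else n - 1


def call_super_enhancers(acetyl: PeakSet, stitch_bp: int = 12_500,
                         tss_exclude: pd.DataFrame | None = None,
                         tss_exclude_bp: int = 2_500) -> SuperEnhancerSet:
    """ROSE-style super-enhancer calling with the tangent-rule cutoff.

    Peaks within ``stitch_bp`` of each other are merged (optionally
    dropping peaks within ``tss_exclude_bp`` of a TSS first) and the
    stitched regions are ranked ascending by total signal.  With both axes
    rescaled to [0, 1], the cutoff is the signal at the first rank where
    the curve's slope reaches 1; regions above it are super-enhancers.
    """
    iv = acetyl.intervals
    if (iv["score"] < 0).any():
        raise ValueError("signal scores must be nonnegative")
    if tss_exclude is not None and len(tss_exclude):
        tss = np.sort(tss_exclude["tss"].to_numpy())
        mids = ((iv["start"] + iv["end"]) // 2).to_numpy()
        pos = np.searchsorted(tss, mids)
        left = tss[np.clip(pos - 1, 0, len(tss) - 1)]
        right = tss[np.clip(pos, 0, len(tss) - 1)]
        near = np.minimum(np.abs(mids - left), np.abs(mids - right)) <= tss_exclude_bp
        iv = iv[~near]
    stitched = _stitch(iv, stitch_bp)
    stitched = stitched.sort_values("signal", kind="stable").reset_index(drop=True)
    stitched["rank"] = np.arange(len(stitched))
    if len(stitched) < 3 or stitched["signal"].max() <= 0:
        warnings.warn("fewer than 3 stitched regions; no cutoff, none flagged super",
                      stacklevel=2)
        stitched["is_super"] = False
        return SuperEnhancerSet(stitched, cutoff_signal=float("inf"), cutoff_rank=-1)
    idx = tangent_cutoff_index(stitched["signal"].to_numpy().astype(float))
    cutoff = float(stitched["signal"].iloc[idx])
    stitched["is_super"] = stitched["signal"] > cutoff
    return SuperEnhancerSet(stitched, cutoff_signal=cutoff, cutoff_rank=idx)


def assign_se_genes(ses: SuperEnhancerSet, genes: pd.DataFrame,
                    window_bp: int = 50_000) -> pd.DataFrame:
    """Proximity assignment: gene joined to an SE iff its TSS lies within
    ``window_bp`` of the SE region."""
    rows = []
    sup = ses.supers()
    for _, se in sup.iterrows():
        lo, hi = se["start"] - window_bp, se["end"] + window_bp
        hit = genes[(genes["chrom"] == se["chrom"]) & (genes["tss"] >= lo)
                    & (genes["tss"] < hi)]
        for gid in hit.index:
            rows.append({"se_rank": se["rank"], "se_start": se["start"],
                         "se_end": se["end"], "gene_id": gid})
    return pd.DataFrame(rows, columns=["se_rank", "se_start", "se_end", "gene_id"])


# ---------------------------------------------------------------------------
# DE tables and qPCR

def classify_de(genes: pd.DataFrame, lfc_thresh: float = 1.0,
                p_thresh: float = 0.01) -> pd.Series:
    """Per-gene up/down/ns class at the given |log2FC| and padj thresholds."""
    up = (genes["log2FC"] >= lfc_thresh) & (genes["padj"] < p_thresh)
    down = (genes["log2FC"] <= -lfc_thresh) & (genes["padj"] < p_thresh)
    out = pd.Series("ns", index=genes.index, name="de_class")
    out[up] = "up"
    out[down] = "down"
    return out


def de_summary(genes: pd.DataFrame, lfc_thresh: float = 1.0,
               p_thresh: float = 0.01) -> dict:
    """Count significantly regulated genes: up, down and their total."""
    cls = classify_de(genes, lfc_thresh=lfc_thresh, p_thresh=p_thresh)
    n_up = int((cls == "up").sum())
    n_down = int((cls == "down").sum())
    return {"n_up": n_up, "n_down": n_down, "n_total": n_up + n_down}


def chip_qpcr_enrichment(ct_ip: float, ct_ref: float) -> float:
    """Comparative-Ct fold enrichment of IP over reference: 2^(Ct_ref - Ct_ip).

    One fewer cycle to threshold means twice the template, so a lower IP Ct
    yields fold > 1.
    """
    return float(2.0 ** (ct_ref - ct_ip))
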