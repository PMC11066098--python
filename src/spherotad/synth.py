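"""Synthetic paired-condition fixtures with machine-readable ground truth.

Generates the two-condition data the comparative pipeline consumes —
contact matrices, peak sets, signal tracks and a gene table — with planted
reorganization events (compartment flips, TAD fusions/splits/shifts,
corner-loop losses, condition-lost CTCF peaks) recorded in a
:class:`SyntheticTruth` so downstream recovery can be scored exactly.

The contact model is a Poisson field on a power-law distance decay,
modulated multiplicatively by compartment checkerboard, same-TAD block and
corner-loop factors:

    lambda(i, j) = depth * (1 + |i-j|)**(-alpha)
                   * comp_factor**(s_i * s_j)
                   * tad_factor**[same TAD]
                   * loop_factor**[loop pixel]

which is exactly the structure compartment eigenvector analysis, insulation
scoring and aggregate pileups assume.  Everything is a pure function of
(config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ContactMatrix, write_contacts, write_bins
from .features import PeakSet
from .tads import TAD, TADSet

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "make_truth",
    "simulate_contacts",
    "simulate_peaks",
    "simulate_genes",
    "write_fixture",
    "truth_tadset",
    "gene_density_track",
    "flip_recovery",
    "tad_event_recovery",
]

CONDITIONS = ("2D", "3D")


@dataclass
class SimConfig:
    """Simulation parameters.  Defaults define the package's standard
    desk-scale study conditions: one 200-Mb chromosome at 100-kb bins with
    a handful of planted events per kind."""

    chrom: str = "chrS"
    n_bins: int = 2000
    bin_size: int = 100_000
    # planted event counts
    n_atob: int = 10
    n_btoa: int = 2
    n_fusions: int = 20
    n_splits: int = 6
    n_shifts: int = 5
    shift_bins: int = 3
    n_corner_loss: int = 25
    # structural scales (bins)
    min_tad_bins: int = 8
    max_tad_bins: int = 30
    # compartment segments group consecutive TADs (alternating A/B sign)
    comp_seg_tads_min: int = 2
    comp_seg_tads_max: int = 3
    # contact model
    depth: float = 1000.0
    alpha: float = 1.0
    comp_factor: float = 1.6
    tad_factor: float = 2.0
    loop_factor: float = 3.0
    # peaks
    ctcf_loss_fraction: float = 0.75
    n_ctcf_background: int = 300
    peak_width_bp: int = 400
    n_pr_2d: int = 400
    n_pr_gain_3d: int = 300
    n_acetyl_background: int = 500
    n_se_clusters: int = 30
    se_cluster_peaks: int = 5
    se_shared_fraction: float = 0.8
    # genes
    n_genes: int = 1000
    n_up: int = 80
    n_down: int = 150
    frac_down_in_fused: float = 0.30
    frac_up_in_fused: float = 0.17
    frac_down_in_atob: float = 0.15
    frac_up_in_btoa: float = 0.10
    frac_down_in_corner_loss: float = 0.25
    a_compartment_gene_bias: float = 3.0
    # reserve corner-loss domains for down genes (keeps control gene sets
    # clear of the planted effect; used by the dedicated corner-loss fixture)
    reserve_corner_loss_tads: bool = False
    # DE thresholds the labels are consistent with
    lfc_thresh: float = 1.0
    p_thresh: float = 0.01

    def __post_init__(self) -> None:
        if self.n_bins < 200:
            raise ValueError("n_bins must be >= 200")


def corner_loss_config(**overrides) -> SimConfig:
    """The dedicated corner-loss study conditions: no compartment flips or
    boundary events, 40 corner-loop losses planted at the domains holding
    the down-regulated genes (80% of them), control genes kept outside."""
    params = dict(n_atob=0, n_btoa=0, n_fusions=0, n_splits=0, n_shifts=0,
                  n_corner_loss=40, frac_down_in_corner_loss=0.8,
                  frac_down_in_fused=0.0, frac_down_in_atob=0.0,
                  frac_up_in_fused=0.0, frac_up_in_btoa=0.0,
                  reserve_corner_loss_tads=True)
    params.update(overrides)
    return SimConfig(**params)


def scaled_config(n_bins: int, **overrides) -> SimConfig:
    """A SimConfig with event/gene/peak counts scaled to a smaller genome,
    keeping per-bin densities comparable to the 2000-bin default."""
    f = n_bins / 2000.0
    base = SimConfig()

    def sc(x, lo=1):
        return max(lo, int(round(x * f)))

    params = dict(
        n_bins=n_bins,
        n_atob=sc(base.n_atob), n_btoa=sc(base.n_btoa),
        n_fusions=sc(base.n_fusions), n_splits=sc(base.n_splits),
        n_shifts=sc(base.n_shifts), n_corner_loss=sc(base.n_corner_loss),
        n_ctcf_background=sc(base.n_ctcf_background),
        n_pr_2d=sc(base.n_pr_2d), n_pr_gain_3d=sc(base.n_pr_gain_3d),
        n_acetyl_background=sc(base.n_acetyl_background),
        n_se_clusters=sc(base.n_se_clusters, lo=3),
        n_genes=sc(base.n_genes, lo=50), n_up=sc(base.n_up, lo=5),
        n_down=sc(base.n_down, lo=10),
    )
    params.update(overrides)
    return SimConfig(**params)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one paired two-condition fixture."""

    config: SimConfig
    seed: int
    compartments: dict            # cond -> per-bin sign array in {+1,-1}
    tad_boundaries: dict          # cond -> sorted bin list, 0 and n_bins included
    events: list                  # dicts: kind, plus kind-specific bin fields
    loops: dict                   # cond -> list of (bin_i, bin_j)
    corner_loss_tads: list        # (start_bin, end_bin) losing their loop in 3D
    peak_truth: dict              # name -> cond -> DataFrame(start, end, score)
    genes: pd.DataFrame           # gene table incl. de_class

    @property
    def n_bins(self) -> int:
        return self.config.n_bins

    def events_of(self, kind: str) -> list:
        return [e for e in self.events if e["kind"] == kind]

    def to_json(self) -> str:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        payload = {
            "config": clean(asdict(self.config)),
            "seed": int(self.seed),
            "compartments": clean({c: v for c, v in self.compartments.items()}),
            "tad_boundaries": clean(self.tad_boundaries),
            "events": clean(self.events),
            "loops": clean(self.loops),
            "corner_loss_tads": clean(self.corner_loss_tads),
            "genes": self.genes.reset_index().to_dict(orient="list"),
            "peak_truth": {name: {c: df.to_dict(orient="list")
                                  for c, df in conds.items()}
                           for name, conds in self.peak_truth.items()},
        }
        return json.dumps(payload, sort_keys=True)


# ---------------------------------------------------------------------------
# truth construction

def _segment_lengths(rng, total, lo, hi):
    out = []
    used = 0
    while used < total:
        L = int(rng.integers(lo, hi + 1))
        if total - (used + L) < lo:
            L = total - used
        out.append(L)
        used += L
    return out


def make_truth(config: SimConfig, seed: int) -> SyntheticTruth:
    """Plant compartment flips, TAD fusions/splits/shifts, corner-loop
    losses and condition-dependent peak/gene structure.

    Raises if a requested event count cannot be placed without overlap,
    naming the event kind.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    n = cfg.n_bins

    # --- 2D TAD boundaries
    sizes = _segment_lengths(rng, n, cfg.min_tad_bins, cfg.max_tad_bins)
    bounds_2d = [0]
    for L in sizes:
        bounds_2d.append(bounds_2d[-1] + L)
    internal = bounds_2d[1:-1]

    # --- 2D compartment segments: groups of 2-3 consecutive TADs with
    # strictly alternating A/B sign.  Compartment borders thereby coincide
    # with TAD boundaries (as in real genomes — and the compartment contrast
    # cannot mimic extra TAD boundaries), while most boundaries stay
    # interior to a segment, leaving room for fusion/shift targets.
    comp_2d = np.empty(n, dtype=int)
    seg_spans = []
    comp_borders: set[int] = set()
    sign = int(rng.integers(0, 2)) * 2 - 1
    t = 0
    n_tads = len(bounds_2d) - 1
    while t < n_tads:
        k = int(rng.integers(cfg.comp_seg_tads_min, cfg.comp_seg_tads_max + 1))
        s0, s1 = bounds_2d[t], bounds_2d[min(t + k, n_tads)]
        comp_2d[s0:s1] = sign
        seg_spans.append((s0, s1, sign))
        comp_borders.update((s0, s1))
        sign = -sign
        t += k

    events: list[dict] = []

    # --- compartment flips: flip whole segments of the right starting sign.
    # Strict sign alternation means two same-direction flips can never be
    # coordinate-adjacent, so each planted flip stays a distinct region.
    comp_3d = comp_2d.copy()

    def pick_flip_segments(sign_wanted, count, kind):
        pool = [s for s in seg_spans if s[2] == sign_wanted]
        if len(pool) < count:
            raise ValueError(f"cannot place {count} {kind} events: only "
                             f"{len(pool)} segments of that sign")
        idx = sorted(rng.choice(len(pool), size=count, replace=False))
        return [pool[i] for i in idx]

    atob = pick_flip_segments(1, cfg.n_atob, "AtoB")
    btoa = pick_flip_segments(-1, cfg.n_btoa, "BtoA")
    for s0, s1, _ in atob:
        comp_3d[s0:s1] = -1
        events.append({"kind": "AtoB", "start_bin": s0, "end_bin": s1})
    for s0, s1, _ in btoa:
        comp_3d[s0:s1] = 1
        events.append({"kind": "BtoA", "start_bin": s0, "end_bin": s1})

    # --- TAD events: draw disjoint boundary/TAD targets on the 2D tiling
    n_needed = cfg.n_fusions + cfg.n_shifts
    # fusions and shifts pick internal boundaries, no two sharing a TAD
    # (adjacent removals would merge into one multi-TAD event); boundaries
    # doubling as compartment borders are excluded, since the compartment
    # contrast would keep insulating the locus after the TAD boundary is gone
    chosen: list[int] = []
    order = rng.permutation(len(internal)) if n_needed else []
    for idx in order:
        if internal[idx] in comp_borders:
            continue
        if idx in chosen or (idx - 1) in chosen or (idx + 1) in chosen:
            continue
        chosen.append(int(idx))
        if len(chosen) == n_needed:
            break
    if len(chosen) < n_needed:
        raise ValueError(f"cannot place {cfg.n_fusions} fusion and "
                         f"{cfg.n_shifts} shift events on {len(internal)} "
                         "internal boundaries without overlap")
    fusion_idx = sorted(chosen[:cfg.n_fusions])
    shift_idx = sorted(chosen[cfg.n_fusions:])
    taken = set(fusion_idx) | set(shift_idx)

    # splits pick 2D TADs untouched by fusions/shifts and wide enough
    min_split_size = 2 * cfg.min_tad_bins
    split_candidates = []
    for t in range(len(bounds_2d) - 1):
        # TAD t is delimited by internal boundaries t-1 and t
        if (t - 1) in taken or t in taken:
            continue
        if bounds_2d[t + 1] - bounds_2d[t] >= min_split_size:
            split_candidates.append(t)
    if len(split_candidates) < cfg.n_splits:
        raise ValueError(f"cannot place {cfg.n_splits} split events: only "
                         f"{len(split_candidates)} eligible TADs")
    split_tads = sorted(rng.choice(split_candidates, cfg.n_splits, replace=False))

    bounds_3d = set(bounds_2d)
    for bi in fusion_idx:
        b = internal[bi]
        bounds_3d.discard(b)
        events.append({"kind": "fusion", "removed_boundary": b,
                       "start_bin": bounds_2d[bi], "end_bin": bounds_2d[bi + 2]})
    for bi in shift_idx:
        b = internal[bi]
        direction = 1 if rng.random() < 0.5 else -1
        new_b = b + direction * cfg.shift_bins
        bounds_3d.discard(b)
        bounds_3d.add(int(new_b))
        events.append({"kind": "shift", "old_boundary": b, "new_boundary": int(new_b),
                       "start_bin": bounds_2d[bi], "end_bin": bounds_2d[bi + 2]})
    for t in split_tads:
        lo, hi = bounds_2d[t], bounds_2d[t + 1]
        new_b = (lo + hi) // 2
        bounds_3d.add(int(new_b))
        events.append({"kind": "split", "added_boundary": int(new_b),
                       "start_bin": lo, "end_bin": hi})
    bounds_3d = sorted(bounds_3d)

    # --- corner loops: every TAD carries one at its (start, end) corner;
    # a chosen set of conserved TADs loses it in 3D
    def corner_pixels(b0, b1):
        # 2x2 pixel block just inside the domain corner
        return [(b0 + di, b1 - 1 - dj) for di in range(2) for dj in range(2)
                if b0 + di < b1 - 1 - dj]

    event_spans = [(e["start_bin"], e["end_bin"]) for e in events
                   if e["kind"] in ("fusion", "split", "shift")]

    def touched(lo, hi):
        return any(lo < e1 and hi > e0 for e0, e1 in event_spans)

    conserved_tads = []
    for t in range(len(bounds_2d) - 1):
        lo, hi = bounds_2d[t], bounds_2d[t + 1]
        if not touched(lo, hi):
            conserved_tads.append((lo, hi))
    if len(conserved_tads) < cfg.n_corner_loss:
        raise ValueError(f"cannot place {cfg.n_corner_loss} corner-loss events: "
                         f"only {len(conserved_tads)} conserved TADs")
    pick = sorted(rng.choice(len(conserved_tads), cfg.n_corner_loss, replace=False))
    corner_loss = [conserved_tads[i] for i in pick]
    loss_set = set(corner_loss)

    loops = {c: [] for c in CONDITIONS}
    for t in range(len(bounds_2d) - 1):
        loops["2D"].extend(corner_pixels(bounds_2d[t], bounds_2d[t + 1]))
    for t in range(len(bounds_3d) - 1):
        lo, hi = bounds_3d[t], bounds_3d[t + 1]
        if (lo, hi) in loss_set:
            continue
        loops["3D"].extend(corner_pixels(lo, hi))

    # --- genes
    genes = _place_genes(cfg, rng, comp_2d, events, corner_loss)

    # --- peaks
    peak_truth = _place_peaks(cfg, rng, bounds_2d, fusion_idx, internal, genes)

    return SyntheticTruth(config=cfg, seed=int(seed),
                          compartments={"2D": comp_2d, "3D": comp_3d},
                          tad_boundaries={"2D": list(map(int, bounds_2d)),
                                          "3D": list(map(int, bounds_3d))},
                          events=events, loops=loops,
                          corner_loss_tads=[tuple(map(int, t)) for t in corner_loss],
                          peak_truth=peak_truth, genes=genes)


def _place_genes(cfg, rng, comp_2d, events, corner_loss):
    n = cfg.n_bins
    bs = cfg.bin_size

    def bins_of(kinds):
        out = []
        for e in events:
            if e["kind"] in kinds:
                out.extend(range(e["start_bin"], e["end_bin"]))
        return np.array(sorted(set(out)), dtype=int)

    fused_bins = bins_of({"fusion"})
    atob_bins = bins_of({"AtoB"})
    btoa_bins = bins_of({"BtoA"})
    loss_bins = np.array(sorted({b for lo, hi in corner_loss
                                 for b in range(lo, hi)}), dtype=int)
    # background placement biased toward the A compartment (active chromatin
    # is gene-dense), which later serves as the orientation reference.
    # Optionally corner-loss domains are reserved for the down-regulated
    # genes the loss is tied to, keeping control gene sets free of the
    # planted effect (the desk-scale analogue of genome-scale dilution).
    w = np.where(comp_2d == 1, cfg.a_compartment_gene_bias, 1.0)
    if cfg.reserve_corner_loss_tads:
        w[loss_bins] = 0.0
    w = w / w.sum()

    rows = []

    def add_genes(cls, k, pool=None):
        if k == 0 or (pool is not None and len(pool) == 0):
            return 0
        if pool is None:
            b = rng.choice(n, size=k, p=w)
        else:
            b = rng.choice(pool, size=k, replace=True)
        for bin_idx in np.atleast_1d(b):
            tss = int(bin_idx) * bs + int(rng.integers(0, bs))
            L = int(rng.integers(5_000, 50_000))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                start, end = tss, tss + L
            else:
                start, end = max(tss - L, 0), tss
            rows.append({"chrom": cfg.chrom, "start": start, "end": end,
                         "strand": strand, "tss": tss, "de_class": cls})
        return len(np.atleast_1d(b))

    placed = add_genes("down", int(round(cfg.frac_down_in_fused * cfg.n_down)),
                       fused_bins)
    placed += add_genes("down", int(round(cfg.frac_down_in_atob * cfg.n_down)),
                        atob_bins)
    placed += add_genes("down", int(round(cfg.frac_down_in_corner_loss * cfg.n_down)),
                        loss_bins)
    add_genes("down", cfg.n_down - placed)
    placed = add_genes("up", int(round(cfg.frac_up_in_fused * cfg.n_up)), fused_bins)
    placed += add_genes("up", int(round(cfg.frac_up_in_btoa * cfg.n_up)), btoa_bins)
    add_genes("up", cfg.n_up - placed)
    add_genes("ns", cfg.n_genes - cfg.n_down - cfg.n_up)

    genes = pd.DataFrame(rows)
    genes.index = [f"gene_{k:05d}" for k in range(len(genes))]
    genes.index.name = "gene_id"
    return genes


def _place_peaks(cfg, rng, bounds_2d, fusion_idx, internal, genes):
    bs = cfg.bin_size
    span = cfg.n_bins * bs
    hw = cfg.peak_width_bp // 2

    def peak_at(pos):
        return (max(int(pos) - hw, 0), int(pos) + hw)

    # CTCF: one peak per 2D boundary (chromosome ends excluded) + background
    fused_bounds = {internal[i] for i in fusion_idx}
    ctcf_rows = []
    for b in internal:
        s, e = peak_at(b * bs)
        ctcf_rows.append({"start": s, "end": e, "at_fused_boundary": b in fused_bounds})
    for pos in rng.integers(0, span, size=cfg.n_ctcf_background):
        s, e = peak_at(pos)
        ctcf_rows.append({"start": s, "end": e, "at_fused_boundary": False})
    ctcf = pd.DataFrame(ctcf_rows).sort_values("start").reset_index(drop=True)
    if cfg.ctcf_loss_fraction > 0:
        lost = (rng.random(len(ctcf)) < cfg.ctcf_loss_fraction) \
            | ctcf["at_fused_boundary"].to_numpy()
    else:
        lost = np.zeros(len(ctcf), dtype=bool)
    ctcf_2d = ctcf[["start", "end"]]
    ctcf_3d = ctcf.loc[~lost, ["start", "end"]].reset_index(drop=True)

    # H3K27ac: background enhancers + clustered high-signal candidates for
    # super-enhancer stitching; cluster sets are mostly shared between
    # conditions with a configurable exclusive fraction each
    # background enhancer positions are shared between conditions (same
    # cell line); only the signal strengths are condition-specific
    bg_pos = np.sort(rng.integers(0, span, size=cfg.n_acetyl_background))

    # most enhancer clusters sit near regulated genes (acetylation marks
    # the enhancers driving the differential program)
    n_shared = int(round(cfg.se_shared_fraction * cfg.n_se_clusters))
    n_excl = cfg.n_se_clusters - n_shared
    n_anchor = n_shared + 2 * n_excl
    de_tss = genes.loc[genes["de_class"] != "ns", "tss"].to_numpy()
    anchors = rng.integers(0, span - 100_000, size=n_anchor)
    if de_tss.size:
        near_de = rng.random(n_anchor) < 0.6
        picks = de_tss[rng.integers(0, len(de_tss), size=n_anchor)] \
            + rng.integers(5_000, 30_000, size=n_anchor)
        anchors = np.where(near_de, np.clip(picks, 0, span - 100_000), anchors)
    cluster_sets = {"2D": list(anchors[:n_shared + n_excl]),
                    "3D": list(anchors[:n_shared]) + list(anchors[n_shared + n_excl:])}
    acetyl = {}
    for cond in CONDITIONS:
        rows = [{"start": peak_at(p)[0], "end": peak_at(p)[1],
                 "score": float(rng.lognormal(1.0, 0.5))} for p in bg_pos]
        for a in cluster_sets[cond]:
            for k in range(cfg.se_cluster_peaks):
                s = int(a) + k * 3_000
                rows.append({"start": s, "end": s + 1_000,
                             "score": float(rng.lognormal(3.3, 0.3))})
        df = pd.DataFrame(rows).sort_values("start").reset_index(drop=True)
        acetyl[cond] = df

    # PR: 3D keeps the 2D sites and gains new ones; half the gained sites
    # land inside 3D acetylated enhancer clusters ("enhancer-associated")
    pr_pos = np.sort(rng.integers(0, span, size=cfg.n_pr_2d))
    n_gain = cfg.n_pr_gain_3d
    gain_bg = rng.integers(0, span, size=n_gain - n_gain // 2)
    cl3 = np.asarray(cluster_sets["3D"])
    if cl3.size:
        at_cluster = cl3[rng.integers(0, len(cl3), size=n_gain // 2)] \
            + rng.integers(0, cfg.se_cluster_peaks * 3_000, size=n_gain // 2)
    else:
        at_cluster = rng.integers(0, span, size=n_gain // 2)
    pr_gain = np.concatenate([gain_bg, at_cluster])
    pr_2d = pd.DataFrame([peak_at(p) for p in pr_pos], columns=["start", "end"])
    pr_3d = pd.DataFrame([peak_at(p) for p in np.sort(np.concatenate([pr_pos, pr_gain]))],
                         columns=["start", "end"])

    return {
        "ctcf": {"2D": ctcf_2d.assign(score=1.0),
                 "3D": ctcf_3d.assign(score=1.0)},
        "pr": {"2D": pr_2d.assign(score=1.0), "3D": pr_3d.assign(score=1.0)},
        "h3k27ac": acetyl,
    }


# ---------------------------------------------------------------------------
# materialization

def _lambda_matrix(truth: SyntheticTruth, condition: str) -> np.ndarray:
    cfg = truth.config
    n = cfg.n_bins
    idx = np.arange(n)
    d = np.abs(np.subtract.outer(idx, idx))
    lam = cfg.depth * (1.0 + d) ** (-cfg.alpha)
    s = truth.compartments[condition]
    lam *= cfg.comp_factor ** np.outer(s, s).astype(float)
    bounds = np.asarray(truth.tad_boundaries[condition])
    tad_id = np.searchsorted(bounds, idx, side="right")
    lam *= np.where(np.equal.outer(tad_id, tad_id), cfg.tad_factor, 1.0)
    for (i, j) in truth.loops[condition]:
        lam[i, j] *= cfg.loop_factor
        lam[j, i] *= cfg.loop_factor
    return lam


def simulate_contacts(truth: SyntheticTruth, condition: str, seed: int) -> ContactMatrix:
    """Draw a symmetric Poisson contact matrix for one condition."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    cfg = truth.config
    lam = _lambda_matrix(truth, condition)
    rng = np.random.default_rng(seed)
    n = cfg.n_bins
    draw = rng.poisson(np.triu(lam))
    values = np.triu(draw) + np.triu(draw, 1).T
    return ContactMatrix(chrom=cfg.chrom, bin_size=cfg.bin_size,
                         values=values.astype(float), state="raw")


def expected_lambda(truth: SyntheticTruth, condition: str) -> np.ndarray:
    """The exact Poisson mean matrix (for marginal checks)."""
    return _lambda_matrix(truth, condition)


def simulate_peaks(truth: SyntheticTruth, condition: str, seed: int) -> dict[str, PeakSet]:
    """Materialize the condition's peak sets as scored PeakSets."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    out = {}
    for name, conds in truth.peak_truth.items():
        df = conds[condition].copy()
        df.insert(0, "chrom", truth.config.chrom)
        if name != "h3k27ac":
            df["score"] = rng.lognormal(2.0, 0.5, size=len(df))
        out[name] = PeakSet(name=f"{name}_{condition}", intervals=df)
    return out


def simulate_genes(truth: SyntheticTruth, seed: int) -> pd.DataFrame:
    """Materialize the gene table with log2FC/padj consistent with the
    planted DE classes at the configured thresholds."""
    cfg = truth.config
    rng = np.random.default_rng(seed)
    genes = truth.genes.copy()
    n = len(genes)
    lfc = rng.normal(0.0, 0.3, size=n)
    padj = rng.uniform(cfg.p_thresh * 1.5, 1.0, size=n)
    up = (genes["de_class"] == "up").to_numpy()
    down = (genes["de_class"] == "down").to_numpy()
    lfc[up] = rng.uniform(cfg.lfc_thresh + 0.5, cfg.lfc_thresh + 4.0, size=up.sum())
    lfc[down] = -rng.uniform(cfg.lfc_thresh + 0.5, cfg.lfc_thresh + 4.0, size=down.sum())
    padj[up | down] = 10.0 ** rng.uniform(-12, np.log10(cfg.p_thresh * 0.5),
                                          size=(up | down).sum())
    genes["log2FC"] = np.round(lfc, 4)
    genes["padj"] = padj
    return genes


def truth_tadset(truth: SyntheticTruth, condition: str) -> TADSet:
    """The planted TAD tiling as a TADSet (for truth-level comparisons)."""
    b = truth.tad_boundaries[condition]
    tads = [TAD(b[k], b[k + 1], float("nan"), float("nan"))
            for k in range(len(b) - 1)]
    return TADSet(chrom=truth.config.chrom, bin_size=truth.config.bin_size,
                  tads=tads)


def gene_density_track(truth: SyntheticTruth, smooth_bins: int = 10) -> np.ndarray:
    """Per-bin gene-TSS density, boxcar-smoothed to compartment scale.

    Compartments live at the megabase scale, so the orientation reference
    is smoothed over ``smooth_bins`` bins; raw per-bin counts are too
    Poisson-noisy to fix the eigenvector sign reliably."""
    bins = (truth.genes["tss"] // truth.config.bin_size).astype(int)
    d = np.bincount(bins[bins < truth.n_bins], minlength=truth.n_bins).astype(float)
    if smooth_bins > 1:
        kern = np.ones(smooth_bins) / smooth_bins
        d = np.convolve(d, kern, mode="same")
    return d


def write_fixture(truth: SyntheticTruth, out_dir, seed: int | None = None) -> dict:
    """Write the complete two-condition fixture; returns a checksum manifest.

    Files: bins.bed, contacts_<cond>.tsv, peaks_<name>_<cond>.bed,
    h3k27ac_<cond>.bedgraph, genes.tsv, truth.json, manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = truth.seed
    cfg = truth.config
    write_bins(cfg.chrom, cfg.bin_size, cfg.n_bins, out / "bins.bed")
    for k, cond in enumerate(CONDITIONS):
        cm = simulate_contacts(truth, cond, seed=seed + 1 + k)
        write_contacts(cm, out / f"contacts_{cond}.tsv")
        peaks = simulate_peaks(truth, cond, seed=seed + 11 + k)
        for name, ps in peaks.items():
            ps.to_bed(out / f"peaks_{name}_{cond}.bed")
        ac = peaks["h3k27ac"].intervals
        ac[["chrom", "start", "end", "score"]].to_csv(
            out / f"h3k27ac_{cond}.bedgraph", sep="\t", header=False,
            index=False, float_format="%.4f")
    genes = simulate_genes(truth, seed=seed + 31)
    genes.reset_index().to_csv(out / "genes.tsv", sep="\t", index=False,
                               float_format="%.6g")
    (out / "truth.json").write_text(truth.to_json())
    manifest = {}
    for p in sorted(out.iterdir()):
        if p.name == "manifest.json":
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# recovery scoring against the planted truth

def _reciprocal_overlap(a0, a1, b0, b1) -> float:
    ov = min(a1, b1) - max(a0, b0)
    if ov <= 0:
        return 0.0
    return ov / max(a1 - a0, b1 - b0)


def flip_recovery(truth: SyntheticTruth, regions, min_recip: float = 0.5) -> dict:
    """Score called compartment-transition regions against planted flips.

    A planted flip is recovered when a called region of the same direction
    overlaps it reciprocally by at least ``min_recip``; called regions
    matching no planted flip count as false."""
    planted = [(e["kind"], e["start_bin"], e["end_bin"])
               for e in truth.events if e["kind"] in ("AtoB", "BtoA")]
    recovered = 0
    matched_regions = set()
    for kind, p0, p1 in planted:
        hit = False
        for ri, r in enumerate(regions):
            if r.kind == kind and _reciprocal_overlap(p0, p1, r.start_bin, r.end_bin) >= min_recip:
                matched_regions.add(ri)
                hit = True
        recovered += hit
    n_false = sum(1 for ri, r in enumerate(regions)
                  if ri not in matched_regions
                  and all(_reciprocal_overlap(p0, p1, r.start_bin, r.end_bin) < min_recip
                          or kind != r.kind
                          for kind, p0, p1 in planted))
    return {"n_planted": len(planted), "n_recovered": recovered,
            "recall": recovered / len(planted) if planted else float("nan"),
            "n_false": n_false}


def tad_event_recovery(truth: SyntheticTruth, changes, match_tol: int = 2) -> dict:
    """Precision/recall of called fused/split/shifted events vs truth.

    A called event matches a planted one when its signature boundary (the
    removed internal boundary for fusions, the added one for splits, the
    old/new pair for shifts) lies within ``match_tol`` bins of the planted
    value."""
    out = {}
    called = {"fusion": [], "split": [], "shift": []}
    for e in changes.events:
        if e.kind == "fused":
            # internal reference boundaries absorbed by the fusion
            called["fusion"].append(e)
        elif e.kind == "split":
            called["split"].append(e)
        elif e.kind == "shifted":
            called["shift"].append(e)

    def event_internal_bounds(ev, which):
        lo, hi = ev.start_bin, ev.end_bin
        return [b for b in (truth.tad_boundaries["2D"] if which == "a"
                            else truth.tad_boundaries["3D"]) if lo < b < hi]

    def contains(ev, b):
        return ev.start_bin - match_tol <= b <= ev.end_bin + match_tol

    for kind, key in (("fusion", "removed_boundary"), ("split", "added_boundary")):
        planted = [e[key] for e in truth.events_of(kind)]
        evs = called[kind]
        n_recalled = sum(any(contains(ev, b) for ev in evs) for b in planted)
        n_true_called = sum(any(contains(ev, b) for b in planted) for ev in evs)
        out[kind] = {
            "recall": n_recalled / len(planted) if planted else float("nan"),
            "precision": n_true_called / len(evs) if evs else float("nan"),
            "n_planted": len(planted), "n_called": len(evs),
        }
    # a moved boundary is witnessed by both of its flanking 1-to-1 events, so
    # several called shifted events may legitimately match one planted shift
    planted_shift = [(e["old_boundary"], e["new_boundary"])
                     for e in truth.events_of("shift")]
    evs = called["shift"]

    def shift_match(ev, pair):
        old, new = pair
        return contains(ev, old) and contains(ev, new)

    n_recalled = sum(any(shift_match(ev, p) for ev in evs) for p in planted_shift)
    n_true_called = sum(any(shift_match(ev, p) for p in planted_shift) for ev in evs)
    out["shift"] = {
        "recall": n_recalled / len(planted_shift) if planted_shift else float("nan"),
        "precision": n_true_called / len(evs) if evs else float("nan"),
        "n_planted": len(planted_shift), "n_called": len(evs),
    }
    return out
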